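"""Minimize a benchmark function with both population optimizers.

The slime-mould optimizer moves candidates toward the incumbent best with
a decaying power-law step and re-seeds its lowest-weight members each
iteration; the chaotic particle swarm drives its randomness through the
logistic map.  Both minimize, here on the 2-D sphere f(x) = x1^2 + x2^2
whose optimum is 0 at the origin.
"""
import numpy as np

from aquadiag import ParameterBox, run_cpso, run_isma

box = ParameterBox(["x1", "x2"], [-5.0, -5.0], [5.0, 5.0])
sphere = lambda x: float(np.sum(x ** 2))

isma = run_isma(sphere, box, seed=0)
cpso = run_cpso(sphere, box, seed=0)

print(f"slime mould : best f = {isma.best_fitness:.3e} at {np.round(isma.best_position, 4)}"
      f"  ({isma.evaluations} evaluations)")
print(f"chaotic PSO : best f = {cpso.best_fitness:.3e} at {np.round(cpso.best_position, 4)}")
print("Both values measure distance-squared from the optimum; smaller is better.")
print("The final slime-mould weight budget was "
      f"lambda = {isma.history[-1].lam:.3f} (weights always sum to lambda).")
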