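# Health thresholds for the diagnosis stage.  Illustrative values
# anchored to typical lake measurement ranges -- editable configuration,
# not science.  "direction" is the harmful side of the bound:
#   above : warn when the value exceeds the bound
#   below : warn when the value falls under the bound
#   band  : warn when the value leaves the [low, high] interval
pH:
  direction: band
  bound: [6.5, 8.5]
DO:
  direction: below
  bound: 5.0
permanganate:
  direction: above
  bound: 10.0
TP:
  direction: above
  bound: 0.2
NH3N:
  direction: above
  bound: 1.5
COD:
  direction: above
  bound: 30.0
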