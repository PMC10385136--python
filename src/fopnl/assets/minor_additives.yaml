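# Ingredients regarded as not contributing substantially to product weight.
# Used to operationalize the "FVNL is the first ingredient and non-FVNL
# ingredients do not substantially contribute to the product's weight" branch
# of the FVNL allocation decision tree. Case-insensitive substring matching.
version: "minor-additives.1"

minor_additive_tokens:
  - salt
  - flavouring
  - flavoring
  - flavour
  - flavor
  - acidity regulator
  - citric acid
  - ascorbic acid
  - antioxidant
  - preservative
  - emulsifier
  - stabilizer
  - stabiliser
  - thickener
  - sweetener
  - colour
  - color
  - vitamin
  - mineral
  - spice
  - herb
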