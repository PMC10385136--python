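# Fiber-bearing ingredient tokens used to decide whether a product with a
# missing fiber declaration plausibly contains fiber (and therefore gets an
# imputed value rather than zero). Case-insensitive substring matching.
version: "fiber-sources.1"

fiber_tokens:
  - inulin
  - psyllium
  - pectin
  - fructooligosaccharide
  - fructo-oligosaccharide
  - oligofructose
  - polydextrose
  - resistant starch
  - beta-glucan
  - cellulose
  - bran
  - whole wheat
  - wholemeal
  - whole grain
  - wholegrain
  - oat
  - barley
  - brown rice
  - chia
  - flaxseed
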