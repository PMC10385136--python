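# Token lexicon for scanning ingredient lists.
#
# An ingredient is flagged as an FVNL source when its name contains one of the
# `fvnl_tokens` (fruit / vegetable / nut / legume names), and additionally as
# concentrated when it also contains one of the `concentrated_markers`.
# Matching is case-insensitive substring matching on the ingredient name.
version: "fvnl-lexicon.1"

fvnl_tokens:
  # fruits
  - apple
  - orange
  - mango
  - pineapple
  - banana
  - grape
  - lime
  - lemon
  - lychee
  - guava
  - passion fruit
  - coconut
  - strawberry
  - berry
  - melon
  - tamarind
  - fruit
  # vegetables
  - carrot
  - tomato
  - pumpkin
  - spinach
  - kale
  - beetroot
  - celery
  - corn
  - potato
  - mushroom
  - vegetable
  # nuts and seeds
  - peanut
  - almond
  - cashew
  - walnut
  - macadamia
  - pistachio
  - sesame
  - nut
  # legumes
  - soybean
  - soy bean
  - mung bean
  - red bean
  - black bean
  - chickpea
  - lentil
  - pea
  - bean

concentrated_markers:
  - concentrate
  - concentrated
  - paste
  - puree from concentrate
  - powder
  - dried
  - dehydrated
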