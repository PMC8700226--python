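# Six-point scheme variant: the four fast-food classes and multi fast
# food collapse into one class.  Pass to `takeaway-cuisine label --scheme`.
collapse_map:
  chicken: multi_fast_food
  kebab: multi_fast_food
  pizza: multi_fast_food
  burger: multi_fast_food
  multi_fast_food: multi_fast_food
  desserts: desserts
  sandwich_cafe_bakery: sandwich_cafe_bakery
  fish_and_chips: fish_and_chips
  south_asian: south_asian
  southeast_east_asian: southeast_east_asian
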