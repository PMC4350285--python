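# Costing constants, all expressed at the 2009/10 price level (AUD).
snap_average_cost: 11582.0       # average SNAP episode cost
snap_inlier_weight: 0.0424       # per-day inlier SNAP weight (same for all classes)
acute_base_excl_ed_icu: 3840.0   # acute base average cost excluding ED and ICU
acute_base_excl_ed: 4092.0       # acute base average cost excluding ED only (default base)
use_base_excl_ed_icu: false      # switch the acute base to 3840 when true
long_stay_flat_rate: 200.0       # per-day rate after the long-stay threshold, uncapped
long_stay_threshold_days: 120    # outlier per-diems stop and the flat rate starts here
ed_average_cost: 396.0           # average cost per ED presentation
ed_mode_weights:                 # relative weights by mode of separation
  admitted: 1.0
  died: 1.0
  discharged: 1.0
concessional_copay: 6.00         # patient co-payment per dispensing where applicable
inflate_copay: false             # add the co-payment at nominal value by default
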