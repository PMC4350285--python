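# Synthetic AR-DRG catalogue. Real per-DRG cost weights, trim points and
# outlier per-diems are published in proprietary casemix costing standards;
# these rows are invented parameters with realistic magnitudes, used by the
# simulator and as the default costing table. Replace with a real table via
# CostParameters.from_files(drg_table=...).
drg_code,care_type,cost_weight,trim_point_days,outlier_per_diem
A01A,acute,5.0,28,800.0
B02B,acute,1.0,20,500.0
C03C,acute,2.2,14,650.0
D04D,acute,0.6,5,300.0
E05E,acute,1.4,10,450.0
SNAP1,snap,,,
SNAP2,snap,,,
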