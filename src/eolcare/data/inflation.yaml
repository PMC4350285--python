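# Derived inflation rates (percent) used to convert medicines and
# medical-service costs to the June 2010 price level.
#
# Medicines rates apply per financial year (July-June); the monthly rate
# is applied for each month remaining in the supply year, then the
# annual rates chain over later financial years.  Service-sector rates
# apply per November-October schedule year (fee schedules update every
# November) and chain over the schedule years following the spend.
medicines:
  annual:
    "2004-05": 0.1519
    "2005-06": 0.2123
    "2006-07": 0.2220
    "2007-08": 0.4832
    "2008-09": 0.1603
    "2009-10": 0.0200
  monthly:
    "2004-05": 0.0126
    "2005-06": 0.0177
    "2006-07": 0.0185
    "2007-08": 0.0402
    "2008-09": 0.0133
    "2009-10": 0.0017
sectors:
  # schedule years run November (of the first calendar year) to October
  mbs:
    "2005-06": 7.0593
    "2006-07": 4.7857
    "2007-08": 2.7389
    "2008-09": 2.3338
    "2009-10": 1.8166
  dental:
    "2005-06": 5.6317
    "2006-07": 4.5525
    "2007-08": 4.5682
    "2008-09": 3.8390
    "2009-10": 4.1654
  other:
    "2005-06": 3.5392
    "2006-07": 3.8714
    "2007-08": 1.1189
    "2008-09": 1.3020
    "2009-10": 5.6757
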