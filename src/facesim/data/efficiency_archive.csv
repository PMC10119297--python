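# Published seasonal fumigation-efficiency record, 2001-2021: percentage of
# fumigation-on minutes with the measured concentration within 10% / 20% of
# the setpoint, pooled over each year's treatment plots. O3 fumigation did
# not run in 2001. Used as reference data and as a self-check that the
# within-10% percentage never exceeds the within-20% percentage.
year,pct10_co2,pct20_co2,pct10_o3,pct20_o3
2001,81.5,92.5,,
2002,73.7,86.2,74.9,89.2
2003,84.7,94.0,80.7,95.2
2004,84.6,95.3,80.9,95.0
2005,81.9,93.0,78.3,94.1
2006,85.0,95.1,82.5,95.7
2007,82.0,93.2,73.4,91.7
2008,82.9,94.0,68.2,87.9
2009,75.7,89.8,57.4,80.3
2010,65.5,87.1,52.2,72.7
2011,78.6,91.2,73.2,90.7
2012,75.6,90.2,71.5,88.2
2013,74.5,89.3,56.6,77.3
2014,78.3,92.0,59.0,82.4
2015,82.3,93.0,55.8,79.4
2016,83.6,94.1,65.6,87.4
2017,85.3,96.0,60.2,82.9
2018,87.9,96.6,61.0,84.0
2019,85.1,95.9,62.5,85.3
2020,82.4,93.8,60.9,83.9
2021,79.4,92.6,63.4,84.2
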