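# Default synthetic viewpoint study.
#
# A ~1.1 Mb random chromosome with mouse-like base composition (58% AT)
# is digested at GATC into ~4000 restriction fragments (~270 bp mean
# width, the density a 4-cutter actually produces).  Two conditions x
# two replicates of distance-decaying negative-binomial counts are drawn
# around a viewpoint near the chromosome centre, with per-sample
# sequencing depths spanning a 4-fold range.  One 100 kb domain starting
# 350 kb downstream of the viewpoint has its expected counts multiplied
# 5-fold in the 'neuron' condition only.

chrom = chrS
chrom_length = 1100000
at_fraction = 0.58
viewpoint_name = VP
viewpoint_position = 550000

roi_radius = 500000
fine_bin = 1000
rebin_factor = 10
exclusion_radius = 50000
n_pairs = 50

amplitude = 1000
half_distance = 5000
exponent = 1.0
dispersion = 5.0

n_replicates = 2
condition_a = esc
condition_b = neuron
depth_min = 0.5
depth_max = 2.0

effect_condition = neuron
effect_offset = 350000
effect_width = 100000
effect_fold = 5.0

# Near-viewpoint asymmetry injection (off by default).
flank_fold = 1.0
flank_side = none
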