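# Age-banded percentile cutoffs for the motion-perception and visual-search
# tasks, from published preliminary reference data for typically developing
# children. Bands are in months ("4y3m-4y7m" = 51-55). The worse direction
# says on which side of the cutoff a score is flagged: "higher" for
# thresholds/times/errors, "lower" for proportions correct.
measures:
  gm_coherence:
    description: global motion coherence threshold (proportion of coherent dots)
    percentile: 10
    worse: higher
    bands:
      - {lo: 51, hi: 55, cutoff: 0.78}
      - {lo: 57, hi: 68, cutoff: 0.69}
      - {lo: 70, hi: 88, cutoff: 0.46}
  mdf_proportion:
    description: motion-defined form proportion correct
    percentile: 10
    worse: lower
    bands:
      - {lo: 51, hi: 55, cutoff: 0.45}
      - {lo: 57, hi: 68, cutoff: 0.63}
      - {lo: 70, hi: 88, cutoff: 0.74}
  ms_speed:
    description: motion speed discrimination threshold (deg/s speed difference)
    percentile: 10
    worse: higher
    bands:
      - {lo: 51, hi: 55, cutoff: 23.80}
      - {lo: 57, hi: 68, cutoff: 20.00}
      - {lo: 70, hi: 88, cutoff: 12.49}
  search_time_5:
    description: visual search time, 4 distracters + target (s)
    percentile: 10
    worse: higher
    bands:
      - {lo: 51, hi: 55, cutoff: 1.38}
      - {lo: 57, hi: 68, cutoff: 1.23}
      - {lo: 70, hi: 88, cutoff: 1.09}
  search_time_10:
    description: visual search time, 9 distracters + target (s)
    percentile: 10
    worse: higher
    bands:
      - {lo: 51, hi: 55, cutoff: 2.75}
      - {lo: 57, hi: 68, cutoff: 2.20}
      - {lo: 70, hi: 88, cutoff: 2.66}
  search_time_20:
    description: visual search time, 19 distracters + target (s)
    percentile: 10
    worse: higher
    bands:
      - {lo: 51, hi: 55, cutoff: 5.91}
      - {lo: 57, hi: 68, cutoff: 5.47}
      - {lo: 70, hi: 88, cutoff: 4.16}
  response_time:
    description: simple reaction-task response time (s)
    percentile: 10
    worse: higher
    bands:
      - {lo: 51, hi: 55, cutoff: 2.54}
      - {lo: 57, hi: 68, cutoff: 2.03}
      - {lo: 70, hi: 88, cutoff: 1.70}
  total_errors:
    description: total false alarms over the three search conditions
    percentile: 10
    worse: higher
    bands:
      - {lo: 51, hi: 55, cutoff: 2}
      - {lo: 57, hi: 68, cutoff: 1}
      - {lo: 70, hi: 88, cutoff: 1}
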