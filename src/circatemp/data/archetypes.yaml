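# Default three-cluster archetype table, version 1.
# Cosinor parameters (mesor/amplitude/period/acrophase), DSP prevalence,
# sleep-onset timing and MEQ score distributions per cluster.
# acrophase_clock and sleep_onset_mean are clock hours after midnight;
# sleep_onset_sd is in minutes.
archetypes:
  - label: cluster1
    mesor: 34.29
    amplitude: 1.02
    period: 25.75
    acrophase_clock: 2.6667    # 02:40
    dsp_prob: 0.46
    sleep_onset_mean: 0.2      # 00:12
    sleep_onset_sd: 63.0
    meq_mean: 12.71
    meq_sd: 4.0
    n_subjects: 100
  - label: cluster2
    mesor: 33.46
    amplitude: 1.38
    period: 25.76
    acrophase_clock: 2.5667    # 02:34
    dsp_prob: 0.68
    sleep_onset_mean: 2.05     # 02:03
    sleep_onset_sd: 84.0
    meq_mean: 12.43
    meq_sd: 4.0
    n_subjects: 130
  - label: cluster3
    mesor: 32.80
    amplitude: 2.09
    period: 25.33
    acrophase_clock: 2.0333    # 02:02
    dsp_prob: 0.37
    sleep_onset_mean: 0.8      # 00:48
    sleep_onset_sd: 71.0
    meq_mean: 14.38
    meq_sd: 4.0
    n_subjects: 51
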