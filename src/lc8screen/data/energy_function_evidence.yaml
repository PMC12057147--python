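# Example evidence ledger: has the structure predictor learned an energy
# function?  Hypotheses: Hs = memorised structures only; Hn = learned the
# natural energy function; Hi = learned an inaccurate energy function that
# shares the natural minima.  Contributions are log-odds in decibels for
# the pairwise comparisons Hn/Hs and Hi/Hs.
evidence:
- id: E1
  description: >-
    1-client scores discriminate nonbinders better than 2-client scores,
    matching the first (half-bound) binding event being the energy barrier.
  contributions: {Hn/Hs: 3, Hi/Hs: 3}
- id: E2
  description: >-
    Across all structures, 2-client binder scores cluster confidently while
    1-client binder scores are bimodal, with the weak peak populated by
    low-ranked structures of weak binders.
  contributions: {Hn/Hs: 6, Hi/Hs: 6}
- id: E3
  description: >-
    A sixth to a half of false positives are AAA anchor mutants of strong
    binders, despite AAA abolishing binding and disfavouring beta-strands.
  contributions: {Hn/Hs: -8, Hi/Hs: 6}
- id: E4
  description: >-
    Scores do not correlate with affinity on the full heterogeneous dataset
    but do on several homogeneous subsets.
  contributions: {Hn/Hs: -2, Hi/Hs: 22}
- id: E5
  description: >-
    Success rates (inclusive cuts) correlate with affinity only within
    homogeneous subsets; the success rate approximates a pseudo-binding
    free energy.
  contributions: {Hn/Hs: 0, Hi/Hs: 18}
- id: E6
  description: >-
    For TQT anchors, individual scores correlate with affinity at lengths 14
    and 16, but the success rate correlates only at length 14.
  contributions: {Hn/Hs: -7, Hi/Hs: 7}
- id: E7
  description: >-
    Several heterogeneous subsets show reasonable R-squared yet no
    relationship by adjusted mutual information.
  contributions: {Hn/Hs: -17, Hi/Hs: -4}
- id: E8
  description: >-
    Affinity correlations are better for 1-client than 2-client predictions
    in nearly all datasets.
  contributions: {Hn/Hs: 10, Hi/Hs: 10}
- id: E9
  description: >-
    The best binning strategy for adjusted mutual information is
    inconsistent across homogeneous subsets.
  contributions: {Hn/Hs: 12, Hi/Hs: 18}
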