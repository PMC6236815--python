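# Default major/minor violation criteria.
#
# Each entry grades one per-fraction dosimetric parameter against a reference
# value with a percentage margin:
#   direction: limit    -> violation when value > reference * (1 + v/100)
#   direction: coverage -> violation when value < reference * (1 - v/100)
# A null reference means "use the planned parameter value of this course"
# (used where no formal absolute planning objective exists). Comparisons are
# strict: a value exactly at the threshold is not a violation. `class` is the
# clinical severity stratum of the criterion itself (target coverage and
# brainstem/spinal-cord sparing are major; target hot spot and parotid
# sparing are minor).
#
# RECONSTRUCTED DEFAULTS: the only absolute anchor recoverable from text is
# the spinal-cord Dmax objective of 48 Gy with a 3% major overdose margin
# (threshold 49.4 Gy). GTV/CTV coverage criteria are copied from the PTV
# criteria (no formal constraints exist for those structures); brainstem
# 54 Gy is an institutional-typical objective; parotid Dmean and the target
# hot spot are graded relative to the planned value. Replace this file with
# your own survey-derived medians for clinical use.

schema: artqa.criteria.v1
criteria:
  - parameter: spinal_cord_dmax_gy
    structure: spinal_cord
    statistic: dmax
    reference: 48.0       # Gy, planning objective
    direction: limit
    v_major: 3.0          # % -> 49.4 Gy
    v_minor: 1.0
    class: major

  - parameter: brainstem_dmax_gy
    structure: brainstem
    statistic: dmax
    reference: 54.0       # Gy, reconstructed institutional-typical objective
    direction: limit
    v_major: 3.0
    v_minor: 1.0
    class: major

  - parameter: ptv_high_d95_gy
    structure: ptv_high
    statistic: d95
    reference: null       # planned value
    direction: coverage
    v_major: 5.0
    v_minor: 2.0
    class: major

  - parameter: ptv_low_d95_gy
    structure: ptv_low
    exclude: ptv_high     # low-dose PTV evaluated excluding the high-dose PTV
    statistic: d95
    reference: null
    direction: coverage
    v_major: 5.0
    v_minor: 2.0
    class: major

  - parameter: gtv_high_d95_gy      # inferred from PTV criteria
    structure: gtv_high
    statistic: d95
    reference: null
    direction: coverage
    v_major: 5.0
    v_minor: 2.0
    class: major

  - parameter: ctv_high_d95_gy      # inferred from PTV criteria
    structure: ctv_high
    statistic: d95
    reference: null
    direction: coverage
    v_major: 5.0
    v_minor: 2.0
    class: major

  - parameter: ctv_low_d95_gy       # inferred from PTV criteria
    structure: ctv_low
    statistic: d95
    reference: null
    direction: coverage
    v_major: 5.0
    v_minor: 2.0
    class: major

  - parameter: ptv_high_dmax_gy     # target hot spot
    structure: ptv_high
    statistic: dmax
    reference: null
    direction: limit
    v_minor: 5.0
    class: minor

  - parameter: parotid_left_dmean_gy
    structure: parotid_left
    statistic: dmean
    reference: null
    direction: limit
    v_minor: 15.0
    class: minor

  - parameter: parotid_right_dmean_gy
    structure: parotid_right
    statistic: dmean
    reference: null
    direction: limit
    v_minor: 15.0
    class: minor

  # Optic structures are major criteria; evaluated only when the structures
  # exist in the course anatomy.
  - parameter: optic_chiasm_dmax_gy
    structure: optic_chiasm
    statistic: dmax
    reference: 54.0
    direction: limit
    v_major: 3.0
    class: major
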