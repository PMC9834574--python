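"""Down-sampling analysis: is the larger group's DE count a power artifact?

Repeatedly draws 17 of the 41 AS samples, reruns the moderated model
against all 17 controls and counts differentially abundant proteins; the
matched-size MR comparison calibrates how much regulation remains once
group sizes are equal.
"""

import valveproteome as vp
from valveproteome.robustness import count_de

cfg = vp.SynthConfig(n_proteins=2000, seed=42)
matrix, meta, _ = vp.generate_cohort(cfg)
matrix, _ = vp.inject_missingness(matrix, cfg)
matrix, _ = vp.filter_valid_values(matrix, meta)
matrix, _ = vp.impute_downshift(matrix, vp.ImputationParams(seed=42))

full_as = count_de(matrix, meta, "AS")
full_mr = count_de(matrix, meta, "MR")
print(f"full-cohort DE counts: AS vs CON = {full_as}, MR vs CON = {full_mr}")

result = vp.downsample_analysis(
    matrix, meta, from_group="AS", n_subset=17, reps=25,
    reference_count=full_mr, seed=42,
)
print(f"AS vs CON at n = 17 (25 repetitions): mean = {result.mean_count:.1f}")
print(f"one-sample t against the MR count {full_mr}: "
      f"t = {result.t_statistic:.2f}, p = {result.p_value:.2e}")
print("\nA mean count still above the size-matched MR comparison shows the"
      "\nexcess AS regulation is not just a sample-size (power) effect.")
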