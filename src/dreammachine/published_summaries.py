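"""Published summary statistics used as inputs to the re-analysis.

The questionnaire study released only summary statistics, not raw ratings:
per-dimension t statistics for the paired comparison of the hallucination-
machine video against control videos (n = 12 participants) and for the
independent comparison against psilocybin ratings from an earlier
pharmacological study (n = 12 vs n = 15), plus two paired comparisons from
the temporal-production session's debrief questionnaire (n = 21).  Bayes
factors and Cohen's d are fully determined by (t, n), so the whole Bayesian
re-analysis runs from these numbers alone via
:func:`dreammachine.experiment_stats.summary_ttest`.

Dimensions missing a psilocybin entry were not compared in the source study.
"""

from __future__ import annotations

#: Paired design, hallucination machine vs control videos, n = 12 (df = 11).
HM_VS_CONTROL_T: dict[str, float] = {
    "intensity": 4.185,
    "patterns": 13.700,
    "imagery": 9.803,
    "mood": 1.685,
    "ego": 2.669,
    "arousal": 4.391,
    "strange": 7.440,
    "vivid": 5.254,
    "time": 0.849,
    "space": 7.005,
    "muddle": 3.183,
    "merge": -1.146,
    "control": 2.218,
    "spirit": 2.715,
    "peace": 2.149,
    "float": 1.008,
    "past": -1.133,
}
HM_VS_CONTROL_N: int = 12

#: Independent design, hallucination machine (n = 12) vs psilocybin (n = 15),
#: pooled df = 25.
HM_VS_PSILOCYBIN_T: dict[str, float] = {
    "intensity": -2.550,
    "patterns": 2.364,
    "ego": 1.335,
    "strange": 2.467,
    "vivid": 0.723,
    "time": -0.820,
    "space": 0.747,
    "muddle": 0.428,
    "merge": 0.364,
    "control": 2.056,
    "spirit": 2.144,
    "peace": 0.688,
    "float": -1.630,
    "past": -0.171,
}
HM_VS_PSILOCYBIN_N: tuple[int, int] = (12, 15)

#: Paired design, temporal-production debrief questionnaire, n = 21 (df = 20).
TIMING_SESSION_T: dict[str, float] = {
    "presence": 3.705,
    "attention": 2.822,
}
TIMING_SESSION_N: int = 21

#: Group-mean produced intervals (s) by target duration from the
#: temporal-production task, used by the inversion screening example.
TIMING_GROUP_MEANS_S: tuple[float, float, float] = (1.75, 2.41, 4.38)
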