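"""Simulated 3-alternative forced-choice depth-judgment experiment.

The model's depth margin for a display is mapped through a softmax decision
rule to probabilities of answering "in front", "behind" or "same plane";
a balanced multi-subject repeated-presentation experiment is then simulated
with multinomial trial outcomes, summarized as conditional response
frequencies, and analyzed with the 2 (edge direction) x 3 (polarity scheme)
factorial ANOVA applied to per-subject response frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy.optimize import minimize

from fgseg.config import ChoiceParams, ExperimentParams
from fgseg.errors import AnalysisError

RESPONSES = ("in_front", "behind", "same_plane")
DIRECTIONS = ("inward", "outward")
SCHEMES = ("all_negative", "all_positive", "mixed")
CONDITIONS = tuple((d, s) for d in DIRECTIONS for s in SCHEMES)

# Observed mean response-frequency triples the default decision rule is
# calibrated against (in_front, behind, same_plane).
OBSERVED_RF = {
    "inward": (0.83, 0.07, 0.10),
    "outward": (0.06, 0.75, 0.19),
}


def choice_probabilities(margin: float, gain: float | None = None,
                         lapse: float | None = None,
                         u_same: float | None = None,
                         params: ChoiceParams | None = None
                         ) -> tuple[float, float, float]:
    """Softmax over utilities (gain*margin, -gain*margin, u_same), lapse-mixed.

    Returns (p_front, p_behind, p_same) on the simplex.  A zero margin gives
    p_front == p_behind by symmetry.
    """
    params = params or ChoiceParams()
    gain = params.gain if gain is None else gain
    lapse = params.lapse if lapse is None else lapse
    u_same = params.u_same if u_same is None else u_same
    if gain <= 0:
        raise ValueError("gain must be positive")
    if not 0 <= lapse < 1:
        raise ValueError("lapse must lie in [0, 1)")
    if not np.isfinite(margin):
        raise ValueError("margin must be finite")
    u = np.array([gain * margin, -gain * margin, u_same])
    e = np.exp(u - u.max())
    p = e / e.sum()
    p = (1 - lapse) * p + lapse / 3.0
    return tuple(float(x) for x in p)


def calibrate_choice_params(margins: dict[str, float],
                            targets: dict[str, tuple] | None = None,
                            lapse: float = 0.0) -> ChoiceParams:
    """Least-squares fit of (gain, u_same) mapping model margins onto observed
    response-frequency triples.

    ``margins`` maps 'inward'/'outward' to the model's depth margins.  The
    returned parameters are the ones stored as package defaults.
    """
    targets = targets or OBSERVED_RF

    def loss(theta):
        g, u = theta
        if g <= 0:
            return 1e6
        err = 0.0
        for cond, m in margins.items():
            p = choice_probabilities(m, gain=g, lapse=lapse, u_same=u)
            err += sum((a - b) ** 2 for a, b in zip(p, targets[cond]))
        return err

    res = minimize(loss, x0=np.array([2.0, -0.5]), method="Nelder-Mead",
                   options={"xatol": 1e-8, "fatol": 1e-12, "maxiter": 2000})
    g, u = res.x
    return ChoiceParams(gain=float(g), u_same=float(u), lapse=lapse)


def _subject_rng(seed: int, subject: int) -> np.random.Generator:
    """Counter-based per-subject substream (Philox keyed on (seed, subject))."""
    return np.random.Generator(
        np.random.Philox(key=np.random.SeedSequence([seed, subject])
                         .generate_state(2, np.uint64).astype(np.uint64)))


def simulate_experiment(probabilities: dict[tuple[str, str], tuple],
                        n_subjects: int = 10, n_reps: int = 4,
                        seed: int = 0) -> pd.DataFrame:
    """Simulate the balanced repeated-presentation 3AFC experiment.

    ``probabilities`` maps (edge_direction, polarity_scheme) conditions to
    response-probability triples.  Every subject sees every condition
    ``n_reps`` times in an independently randomized trial order; responses
    are multinomial.  Fully reproducible for a fixed seed.
    """
    conds = list(probabilities)
    for c, p in probabilities.items():
        p = np.asarray(p, dtype=float)
        if p.shape != (3,) or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(f"probabilities for {c} are not on the simplex")
    rows = []
    for sid in range(n_subjects):
        rng = _subject_rng(seed, sid)
        trials = [(c, r) for c in conds for r in range(n_reps)]
        order = rng.permutation(len(trials))
        for t in order:
            cond, rep = trials[t]
            p = np.asarray(probabilities[cond], dtype=float)
            resp = RESPONSES[rng.choice(3, p=p / p.sum())]
            rows.append({"subject_id": sid,
                         "edge_direction": cond[0],
                         "polarity_scheme": cond[1],
                         "repetition": rep,
                         "response": resp,
                         "seed": seed})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class FrequencyTable:
    """Across-subject mean response frequencies and SEMs per condition."""

    means: pd.DataFrame       # index: condition; columns: rf_<response>
    sems: pd.DataFrame
    per_subject: pd.DataFrame  # subject x condition response frequencies


def response_frequencies(trials: pd.DataFrame) -> FrequencyTable:
    """Conditional response frequencies: per subject, then mean/SEM across.

    Raises :class:`AnalysisError` on an unbalanced design.
    """
    if trials.empty:
        raise AnalysisError("empty trial table")
    cond_cols = ["edge_direction", "polarity_scheme"]
    counts = trials.groupby(["subject_id", *cond_cols]).size()
    if counts.nunique() != 1:
        raise AnalysisError("unbalanced design: unequal trials per cell")
    n_per = int(counts.iloc[0])
    per = (trials.groupby(["subject_id", *cond_cols])["response"]
           .value_counts().unstack(fill_value=0)
           .reindex(columns=list(RESPONSES), fill_value=0) / n_per)
    per.columns = [f"rf_{c}" for c in per.columns]
    per = per.reset_index()
    means = per.groupby(cond_cols).mean(numeric_only=True).drop(
        columns=["subject_id"])
    sems = per.groupby(cond_cols).sem(numeric_only=True).drop(
        columns=["subject_id"])
    return FrequencyTable(means=means, sems=sems, per_subject=per)


def anova_2x3(freq_by_subject: pd.DataFrame) -> dict:
    """Two-way fixed-effects ANOVA on per-subject response frequencies.

    Expects the ``per_subject`` table of :func:`response_frequencies` (one row
    per subject x condition).  Returns, for each of the 'in front' and
    'behind' response dimensions, F and p for the edge-direction and polarity
    main effects.
    """
    need = {"edge_direction", "polarity_scheme", "rf_in_front", "rf_behind"}
    if not need.issubset(freq_by_subject.columns):
        raise AnalysisError(f"missing columns: {need - set(freq_by_subject.columns)}")
    if freq_by_subject["edge_direction"].nunique() != 2 \
            or freq_by_subject["polarity_scheme"].nunique() != 3:
        raise AnalysisError("need the full 2x3 factorial design")
    out = {}
    for resp in ("in_front", "behind"):
        col = f"rf_{resp}"
        if float(freq_by_subject[col].var()) == 0.0:
            raise AnalysisError(f"zero variance in {col}")
        model = smf.ols(
            f"{col} ~ C(edge_direction) * C(polarity_scheme)",
            data=freq_by_subject).fit()
        table = sm.stats.anova_lm(model, typ=2)
        out[resp] = {
            "direction": {
                "F": float(table.loc["C(edge_direction)", "F"]),
                "p": float(table.loc["C(edge_direction)", "PR(>F)"]),
            },
            "polarity": {
                "F": float(table.loc["C(polarity_scheme)", "F"]),
                "p": float(table.loc["C(polarity_scheme)", "PR(>F)"]),
            },
        }
    return out


def run_synthetic_experiment(margins: dict[tuple[str, str], float],
                             choice: ChoiceParams | None = None,
                             design: ExperimentParams | None = None):
    """End-to-end: margins -> choice probabilities -> trials -> summary + ANOVA."""
    choice = choice or ChoiceParams()
    design = design or ExperimentParams()
    probs = {cond: choice_probabilities(m, params=choice)
             for cond, m in margins.items()}
    trials = simulate_experiment(probs, n_subjects=design.n_subjects,
                                 n_reps=design.n_reps, seed=design.seed)
    freqs = response_frequencies(trials)
    stats = anova_2x3(freqs.per_subject)
    return trials, freqs, stats
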