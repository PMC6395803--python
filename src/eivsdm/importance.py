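"""Permutation variable importance and paired model comparisons.

Importance of a predictor follows the shuffle-and-correlate convention:
the predictor column is permuted, the model re-predicts, and importance is
1 minus the Pearson correlation between original and shuffled-column
predictions (mean correlation over permutations, clipped into [0, 1]
before subtraction).  A variable the model ignores therefore scores 0 and
a variable the predictions fully depend on scores near 1; importances
within a model need not sum to one.

Predictor-set comparisons across species use two-sided paired Wilcoxon
signed-rank tests with Holm step-down adjustment.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import wilcoxon
from statsmodels.stats.multitest import multipletests

from .engines import FittedSDM, _predict_array, _validate_matrix

__all__ = [
    "permutation_importance",
    "importance_table",
    "normalised_importances",
    "pairwise_wilcoxon_holm",
    "shannon_evenness",
]

logger = logging.getLogger(__name__)


def permutation_importance(
    model: FittedSDM,
    X: pd.DataFrame,
    variable: str,
    n_permutations: int = 10,
    seed: int = 0,
) -> float:
    """Importance of one predictor by the permutation/correlation rule."""
    if variable not in model.spec.predictor_names:
        raise ValueError(
            f"{variable!r} is not a predictor of this model "
            f"({model.spec.predictor_names})"
        )
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    Xv = _validate_matrix(model.spec, X).to_numpy(dtype=float)
    orig = _predict_array(model, Xv)
    if np.std(orig) == 0:
        return 0.0
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    j = model.spec.predictor_names.index(variable)
    col = Xv[:, j].copy()
    oc = orig - orig.mean()
    on = np.sqrt((oc**2).sum())
    rs = []
    Xp = Xv.copy()
    for _ in range(n_permutations):
        Xp[:, j] = rng.permutation(col)
        shuffled = _predict_array(model, Xp)
        if np.array_equal(shuffled, orig):  # variable is ignored
            rs.append(1.0)
            continue
        sc = shuffled - shuffled.mean()
        sn = np.sqrt((sc**2).sum())
        rs.append(0.0 if sn == 0 else float(oc @ sc / (on * sn)))
    mean_r = float(np.clip(np.mean(rs), 0.0, 1.0))
    return 1.0 - mean_r


def importance_table(
    model: FittedSDM,
    X: pd.DataFrame,
    n_permutations: int = 10,
    seed: int = 0,
) -> pd.Series:
    """Permutation importance for every predictor of a fitted model.

    Per-variable seeds are derived from the master seed so results do not
    depend on evaluation order.
    """
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(model.spec.predictor_names))
    out = {}
    for name, child in zip(model.spec.predictor_names, children):
        out[name] = permutation_importance(
            model, X, name, n_permutations=n_permutations,
            seed=int(child.generate_state(1)[0]) & 0x7FFFFFFF,
        )
    return pd.Series(out, name="importance")


def normalised_importances(raw: pd.Series) -> pd.Series:
    """Importances rescaled to fractions summing to 1 (all-zero input
    stays all-zero)."""
    total = raw.sum()
    if total == 0:
        return raw.copy()
    return raw / total


def shannon_evenness(values) -> float:
    """Pielou's evenness of a nonnegative importance profile: Shannon
    entropy of the normalised values divided by log(k)."""
    v = np.asarray(values, dtype=float)
    if (v < 0).any():
        raise ValueError("importances must be nonnegative")
    total = v.sum()
    if total == 0 or len(v) < 2:
        return 0.0
    p = v / total
    p = p[p > 0]
    return float(-(p * np.log(p)).sum() / np.log(len(v)))


def pairwise_wilcoxon_holm(
    metric_table: pd.DataFrame,
    reference_set: str | None = None,
    all_pairs: bool = False,
) -> pd.DataFrame:
    """Paired Wilcoxon signed-rank tests between predictor-set columns.

    Rows of ``metric_table`` are species, columns are predictor sets.
    With ``all_pairs`` every unordered pair is tested, otherwise each
    column is tested against ``reference_set``.  P-values are adjusted by
    Holm's step-down method over the whole family.  Pairs whose paired
    differences are all zero get p = 1 by convention.
    """
    cols = list(metric_table.columns)
    if all_pairs:
        pairs = [(a, b) for i, a in enumerate(cols) for b in cols[i + 1:]]
    else:
        if reference_set is None:
            raise ValueError("reference_set required unless all_pairs=True")
        if reference_set not in cols:
            raise ValueError(f"reference set {reference_set!r} not a column")
        pairs = [(c, reference_set) for c in cols if c != reference_set]
    if not pairs:
        raise ValueError("no column pairs to compare")

    rows = []
    for a, b in pairs:
        sub = metric_table[[a, b]].dropna()
        d = sub[a].to_numpy(dtype=float) - sub[b].to_numpy(dtype=float)
        if len(d) < 6:
            raise ValueError(
                f"need >= 6 complete species rows for ({a}, {b}), "
                f"got {len(d)}"
            )
        if np.all(d == 0):
            logger.info("all paired differences zero for (%s, %s)", a, b)
            stat, p = 0.0, 1.0
        else:
            stat, p = wilcoxon(d, alternative="two-sided")
        rows.append({"set_a": a, "set_b": b, "statistic": float(stat),
                     "p_raw": float(p), "n": len(d)})
    out = pd.DataFrame(rows)
    out["p_holm"] = multipletests(out["p_raw"], method="holm")[1]
    return out
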