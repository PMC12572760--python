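"""Population-vector discriminability of go vs no-go odor mixtures.

For each of the 8 mixtures (4 variable backgrounds x {go, no-go} target)
the population vector is the per-glomerulus mean z over the 500 ms window
after target onset, averaged over correct trials, then normalized to unit
length.  Separability is quantified as the maximum dot product with the
mixtures of the opposite valence (nearest-opposite-valence similarity);
training-related change is tested with an exact two-sided sign test on
the count of (animal, mixture) pairs whose similarity decreased.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exact_stats import TestResult, sign_test_exact

__all__ = [
    "SimilarityReport",
    "select_included_glomeruli",
    "build_population_vectors",
    "nearest_opposite_similarity",
    "compare_conditions",
]

INCLUSION_THRESHOLD_Z = 1.0
VECTOR_WINDOW = "target_500ms"
CORRECT_OUTCOMES = ("hit", "correct_rejection")


def _check_window(resp: pd.DataFrame, window: str) -> pd.DataFrame:
    sub = resp[resp["window"] == window]
    if sub.empty:
        raise ValueError(f"ResponseTable has no rows for window {window!r}")
    return sub


def select_included_glomeruli(
    resp: pd.DataFrame,
    threshold: float = INCLUSION_THRESHOLD_Z,
    window: str = VECTOR_WINDOW,
    correct_only: bool = True,
) -> pd.DataFrame:
    """(animal_id, roi_id) pairs whose trial-averaged response to ANY
    mixture exceeds the threshold (strict >) in any condition present.

    The rule is evaluated per animal — ROI labels are only meaningful
    within an animal — and jointly across that animal's conditions so
    population vectors are comparable between naive and expert.
    """
    sub = _check_window(resp, window)
    if correct_only:
        sub = sub[sub["outcome"].isin(CORRECT_OUTCOMES)]
    avg = sub.groupby(["animal_id", "condition", "mixture_id", "roi_id"])["mean_z"].mean()
    best = avg.groupby(["animal_id", "roi_id"]).max()
    pairs = best[best > threshold].reset_index()[["animal_id", "roi_id"]]
    if pairs.empty:
        raise ValueError(
            f"no glomerulus exceeds the inclusion threshold ({threshold} z); "
            "review the threshold or the responses"
        )
    return pairs.sort_values(["animal_id", "roi_id"]).reset_index(drop=True)


def filter_included(resp: pd.DataFrame, included) -> pd.DataFrame:
    """Restrict a ResponseTable to included glomeruli.

    ``included`` is either the (animal_id, roi_id) pair table from
    :func:`select_included_glomeruli` or a plain array of ROI ids (useful
    for single-animal tables and hand-built examples).
    """
    if isinstance(included, pd.DataFrame):
        return resp.merge(included, on=["animal_id", "roi_id"], how="inner")
    return resp[resp["roi_id"].isin(np.asarray(included))]


def build_population_vectors(
    resp: pd.DataFrame,
    included: np.ndarray,
    window: str = VECTOR_WINDOW,
    correct_only: bool = True,
    strict: bool = True,
) -> pd.DataFrame:
    """Unit-normalized mixture x ROI matrix of trial-averaged responses.

    Rows indexed by mixture_id with a ``valence`` column attached as an
    index level; columns are the included ROIs (identical set for every
    mixture).  Raises on mixtures without correct trials and on
    zero-norm vectors rather than normalizing silently; with
    ``strict=False`` such mixtures are dropped instead (the per-mixture
    precondition simply fails for them), which suits subgroup analyses
    on few trials.
    """
    sub = _check_window(resp, window)
    sub = filter_included(sub, included)
    if correct_only:
        sub = sub[sub["outcome"].isin(CORRECT_OUTCOMES)]
    all_mixtures = resp["mixture_id"].unique()
    missing = set(all_mixtures) - set(sub["mixture_id"].unique())
    if missing and strict:
        raise ValueError(f"no correct trials for mixture(s): {sorted(missing)}")
    if sub.empty:
        raise ValueError("no trials left to build population vectors from")
    mat = sub.pivot_table(index="mixture_id", columns="roi_id", values="mean_z", aggfunc="mean")
    if isinstance(included, pd.DataFrame):
        animals = sub["animal_id"].unique()
        cols = np.sort(included.loc[included["animal_id"].isin(animals), "roi_id"].unique())
    else:
        cols = np.sort(np.asarray(included))
    mat = mat.reindex(columns=cols)
    if mat.isna().any().any():
        raise ValueError("missing (mixture, roi) responses; cannot form population vectors")
    valence = sub.drop_duplicates("mixture_id").set_index("mixture_id")["valence"]
    norms = np.linalg.norm(mat.to_numpy(), axis=1)
    if np.any(norms == 0):
        bad = mat.index[norms == 0].tolist()
        if strict:
            raise ValueError(f"zero-norm population vector for mixture(s) {bad}")
        mat = mat.loc[norms > 0]
        norms = norms[norms > 0]
    unit = mat.div(norms, axis=0)
    unit.index = pd.MultiIndex.from_arrays(
        [unit.index, valence.loc[unit.index]], names=["mixture_id", "valence"]
    )
    return unit


def nearest_opposite_similarity(vectors: pd.DataFrame) -> pd.Series:
    """Per mixture, the max dot product with the opposite-valence vectors."""
    valences = vectors.index.get_level_values("valence")
    if len(set(valences)) < 2:
        raise ValueError("need population vectors of both valences")
    v = vectors.to_numpy()
    gram = v @ v.T
    out = {}
    for i, (mix, val) in enumerate(vectors.index):
        opp = np.flatnonzero(valences != val)
        out[mix] = float(gram[i, opp].max())
    return pd.Series(out, name="nearest_opposite_similarity")


@dataclass
class SimilarityReport:
    """Paired per-(animal, mixture) similarities and the sign test."""

    table: pd.DataFrame  # animal_id, mixture_id, sim_a, sim_b, delta
    k_decreased: int
    n: int
    n_ties: int
    sign_test: TestResult


def compare_conditions(sim_a: pd.DataFrame, sim_b: pd.DataFrame) -> SimilarityReport:
    """Paired comparison of nearest-opposite similarities (a = reference
    condition, e.g. naive; b = comparison, e.g. expert).

    ``sim_*`` are DataFrames with columns (animal_id, mixture_id,
    similarity).  k counts pairs with sim_b < sim_a; exact ties are
    dropped from n.  Two-sided exact sign test.
    """
    merged = sim_a.merge(sim_b, on=["animal_id", "mixture_id"], suffixes=("_a", "_b"),
                         validate="one_to_one")
    if merged.empty:
        raise ValueError("no paired (animal, mixture) entries to compare")
    merged["delta"] = merged["similarity_b"] - merged["similarity_a"]
    ties = int((merged["delta"] == 0).sum())
    informative = merged[merged["delta"] != 0]
    n = len(informative)
    if n == 0:
        raise ValueError("all pairs are exact ties; sign test undefined")
    k = int((informative["delta"] < 0).sum())
    return SimilarityReport(table=merged, k_decreased=k, n=n, n_ties=ties,
                            sign_test=sign_test_exact(k, n))
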