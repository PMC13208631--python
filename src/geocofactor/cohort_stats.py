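"""Structure-level aggregation and Fe-vs-Ni cohort comparison.

Per-site sphere profiles are averaged to one row per (structure, metal
class) — structure-level inference avoids weighting a protein by its
number of metal centres.  The aggregated amino-acid frequency vectors feed
a mean-centred PCA, and cysteine usage is compared between Fe- and
Ni-class rows with a two-sided Welch's t-test, either restricted to
enzyme families that carry both metals (the shared-family comparison) or
over the full cohort (the global comparison).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from geocofactor.coordination_sphere import AA_ORDER

__all__ = [
    "FREQ_COLUMNS",
    "PCAResult",
    "SHARED_FAMILIES",
    "WelchResult",
    "aggregate",
    "run_pca",
    "welch_test",
]

FREQ_COLUMNS = [f"freq_{aa}" for aa in AA_ORDER]

#: Enzyme families represented by both Fe and Ni structures; the
#: shared-family cysteine comparison is restricted to these.
SHARED_FAMILIES = ("ACS", "CODH", "NiFe-hydrogenase")


@dataclass(frozen=True)
class PCAResult:
    """Mean-centred PCA of the cohort frequency vectors."""

    loadings: pd.DataFrame  # amino acid x component
    scores: pd.DataFrame  # row x component
    explained_variance_ratio: np.ndarray


@dataclass(frozen=True)
class WelchResult:
    """Two-sided Welch's t-test between the Fe and Ni groups."""

    feature: str
    grouping: str
    t_statistic: float
    degrees_of_freedom: float
    p_value: float
    n_fe: int
    n_ni: int
    mean_fe: float
    mean_ni: float
    degenerate: bool = False


def aggregate(
    profiles: pd.DataFrame,
    metadata: Mapping[str, str] | None = None,
    class_rule: str = "ni",
) -> pd.DataFrame:
    """Average site profiles to one row per (structure, metal class).

    Parameters
    ----------
    profiles:
        Site-level table as produced by
        :func:`geocofactor.coordination_sphere.profile_structures`.
    metadata:
        structure_id → enzyme family; structures absent from the map are
        labelled ``"unassigned"``.
    class_rule:
        How mixed NiFe centres count: ``"ni"`` (default, NiFe active
        centres group with the Ni cohort), ``"fe"``, or ``"dual"`` (count
        toward both classes).

    Empty-sphere sites (``n_residues == 0``) are excluded before
    averaging.  The unweighted mean of frequency vectors again sums to 1.
    """
    if class_rule not in ("ni", "fe", "dual"):
        raise ValueError(f"unknown class_rule {class_rule!r}")
    metadata = dict(metadata or {})
    usable = profiles[profiles["n_residues"] > 0].copy()
    if class_rule == "dual":
        mixed = usable[usable["metal_class"] == "FeNi"]
        as_fe = mixed.assign(metal_class="Fe")
        as_ni = mixed.assign(metal_class="Ni")
        usable = pd.concat(
            [usable[usable["metal_class"] != "FeNi"], as_fe, as_ni],
            ignore_index=True,
        )
    else:
        usable["metal_class"] = usable["metal_class"].replace(
            "FeNi", class_rule.capitalize()
        )
    value_cols = ["hydropathy_mean", "hydropathy_sd"] + FREQ_COLUMNS
    grouped = (
        usable.groupby(["structure_id", "metal_class"], sort=True)[value_cols]
        .mean()
        .reset_index()
    )
    grouped["enzyme_family"] = grouped["structure_id"].map(
        lambda sid: metadata.get(sid, "unassigned")
    )
    cols = ["structure_id", "metal_class", "enzyme_family"] + value_cols
    return grouped[cols]


def run_pca(table: pd.DataFrame, n_components: int | None = None) -> PCAResult:
    """Mean-centred PCA of the aggregated frequency vectors.

    No variance scaling is applied (the inputs are compositional fractions
    on a common scale).  Component signs are fixed by making each
    component's largest-magnitude loading positive, so results are fully
    deterministic.  With all components retained, the explained-variance
    ratios sum to 1 and the centred data are exactly reconstructible.
    """
    from sklearn.decomposition import PCA

    if len(table) < 2:
        raise ValueError("PCA needs at least 2 rows")
    X = table[FREQ_COLUMNS].to_numpy(dtype=float)
    max_rank = min(len(table) - 1, X.shape[1])
    if n_components is None:
        n_components = max_rank
    if n_components > max_rank:
        raise ValueError(f"n_components must be <= {max_rank}")
    if np.allclose(X.var(axis=0), 0):
        raise ValueError("zero total variance: all rows identical")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    loadings = pca.components_.T.copy()  # aa x component
    for j in range(loadings.shape[1]):
        i = np.argmax(np.abs(loadings[:, j]))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    comp_names = [f"PC{i + 1}" for i in range(n_components)]
    return PCAResult(
        loadings=pd.DataFrame(loadings, index=list(AA_ORDER), columns=comp_names),
        scores=pd.DataFrame(scores, index=table.index, columns=comp_names),
        explained_variance_ratio=pca.explained_variance_ratio_.copy(),
    )


def welch_test(
    table: pd.DataFrame,
    feature: str = "C",
    grouping: str = "global",
    families: Sequence[str] = SHARED_FAMILIES,
) -> WelchResult:
    """Welch's t-test on one amino-acid fraction between Fe and Ni rows.

    ``grouping="shared_family"`` restricts the comparison to rows whose
    enzyme family appears in ``families``; ``"global"`` uses all rows.
    Zero variance in both groups is flagged as degenerate rather than
    reported as an ordinary test result.
    """
    if grouping not in ("global", "shared_family"):
        raise ValueError(f"unknown grouping {grouping!r}")
    column = f"freq_{feature}" if len(feature) == 1 else feature
    if column not in table.columns:
        raise KeyError(f"feature column {column!r} not in table")
    rows = table
    if grouping == "shared_family":
        rows = table[table["enzyme_family"].isin(families)]
    fe = rows.loc[rows["metal_class"] == "Fe", column].to_numpy(dtype=float)
    ni = rows.loc[rows["metal_class"] == "Ni", column].to_numpy(dtype=float)
    for label, group in (("Fe", fe), ("Ni", ni)):
        if len(group) < 2:
            raise ValueError(
                f"{label} group has {len(group)} rows after {grouping} "
                "filtering; need at least 2"
            )
    if fe.var(ddof=1) == 0 and ni.var(ddof=1) == 0:
        same = fe.mean() == ni.mean()
        return WelchResult(
            feature=feature,
            grouping=grouping,
            t_statistic=0.0 if same else math_inf_signed(fe.mean() - ni.mean()),
            degrees_of_freedom=float("nan"),
            p_value=1.0 if same else 0.0,
            n_fe=len(fe),
            n_ni=len(ni),
            mean_fe=float(fe.mean()),
            mean_ni=float(ni.mean()),
            degenerate=True,
        )
    result = stats.ttest_ind(fe, ni, equal_var=False)
    return WelchResult(
        feature=feature,
        grouping=grouping,
        t_statistic=float(result.statistic),
        degrees_of_freedom=float(result.df),
        p_value=float(result.pvalue),
        n_fe=len(fe),
        n_ni=len(ni),
        mean_fe=float(fe.mean()),
        mean_ni=float(ni.mean()),
    )


def math_inf_signed(delta: float) -> float:
    return float("inf") if delta > 0 else float("-inf")
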