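"""Healthy reference intervals, per-sample screening flags, phenotype
panels and cohort-structure summaries.

Screening logic: a patient sample is flagged for a target protein when its
%beta-actin level falls below the healthy reference, either strictly below
the reference minimum (``below_group_min``, the default — the reference
table prints a Min column for exactly this comparison) or more than
``z_cut`` reference SDs below the reference mean (``zscore_threshold``).
An observation censored at the detection limit is always flagged.  When no
healthy reference exists for the protein (the reference cohort never
detected it), the rule returns ``not_evaluable`` and screening falls back
to the phenotype panels.

Phenotype panels score cell-population reductions (T-cell lymphopenia,
thrombocytopenia, neutropenia) as the mean z-score of the panel's surface
markers against the healthy-newborn reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator
from sklearn.decomposition import PCA

from .matrix import NormalizedMatrix, ReferenceStats, ValidationError

#: cell-population marker panels (gene symbols; common protein aliases in
#: parentheses: ITGA2B=CD41, GP1BA=CD42b, ITGAM=CD11b, ITGB2=CD18,
#: CEACAM8=CD66b)
DEFAULT_PANELS: dict[str, list[str]] = {
    "t_cell": ["CD2", "CD3D", "CD3E", "CD5", "CD247"],
    "platelet": ["ITGA2B", "GP1BA"],
    "neutrophil": ["ITGAM", "ITGB2", "CD33", "CEACAM8"],
}


@dataclass
class FlagRule:
    """Deficiency-screening rule applied per (sample, protein)."""

    rule_name: str = "below_group_min"
    z_cut: float = -3.0

    def __post_init__(self) -> None:
        if self.rule_name not in ("below_group_min", "zscore_threshold"):
            raise ValidationError(
                "rule_name must be 'below_group_min' or 'zscore_threshold'"
            )
        if self.z_cut >= 0:
            raise ValidationError("z_cut must be negative for deficiency screening")


@dataclass
class PhenotypePanel:
    panel_name: str
    members: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.members:
            raise ValidationError(f"panel {self.panel_name!r} has no members")


# ---------------------------------------------------------------------------
# reference statistics
# ---------------------------------------------------------------------------


def compute_reference(
    normalized: NormalizedMatrix, meta: pd.DataFrame, group: str
) -> ReferenceStats:
    """Per-protein mean, sample SD and minimum over one healthy group.

    Censored (below-LOD) cells are excluded from the statistics; a protein
    with fewer than 2 numeric observations in the group gets NaN stats
    (no reference interval).
    """
    samples = meta.index[meta["group"] == group]
    if len(samples) == 0:
        raise ValidationError(f"no samples in group {group!r}")
    if len(samples) < 2:
        raise ValidationError(f"group {group!r} needs >= 2 samples for an SD")
    sub = normalized.values[list(samples)]
    n = sub.notna().sum(axis=1)
    table = pd.DataFrame(
        {
            "mean": sub.mean(axis=1),
            "sd": sub.std(axis=1, ddof=1),
            "min": sub.min(axis=1),
            "n": n,
        }
    )
    table.loc[n < 2, ["mean", "sd", "min"]] = np.nan
    return ReferenceStats(group, table)


# ---------------------------------------------------------------------------
# flagging
# ---------------------------------------------------------------------------


def flag_sample(
    value: float,
    below_lod: bool,
    reference_row: pd.Series | None,
    rule: FlagRule | None = None,
) -> tuple[bool | None, str]:
    """Flag one observation against its healthy reference.

    Returns (flag, rationale); flag is None when the protein has no
    reference interval (``not_evaluable``).
    """
    rule = rule or FlagRule()
    if reference_row is None or pd.isna(reference_row["mean"]):
        return None, "not_evaluable: no healthy reference interval"
    if below_lod:
        return True, "below detection limit"
    if pd.isna(value):
        return None, "not_evaluable: value missing"
    if rule.rule_name == "below_group_min":
        ref_min = float(reference_row["min"])
        if value < ref_min:
            return True, f"value {value:g} < reference minimum {ref_min:g}"
        return False, f"value {value:g} >= reference minimum {ref_min:g}"
    mean, sd = float(reference_row["mean"]), float(reference_row["sd"])
    if sd == 0 or pd.isna(sd):
        return None, "not_evaluable: reference SD unavailable"
    z = (value - mean) / sd
    if z < rule.z_cut:
        return True, f"z {z:.2f} < cutoff {rule.z_cut:g}"
    return False, f"z {z:.2f} >= cutoff {rule.z_cut:g}"


class ReferenceIntervalScreen(BaseEstimator):
    """Fit healthy reference intervals, then flag query samples.

    ``fit(normalized, meta)`` computes per-protein reference statistics on
    the configured healthy group; ``predict(values, below_lod)`` returns a
    boolean protein x sample frame of deficiency flags (NaN where not
    evaluable), and ``screen_targets`` produces the per-sample report for
    named causative proteins.
    """

    def __init__(self, rule_name: str = "below_group_min", z_cut: float = -3.0,
                 reference_group: str = "healthy_newborn"):
        self.rule_name = rule_name
        self.z_cut = z_cut
        self.reference_group = reference_group

    def _rule(self) -> FlagRule:
        return FlagRule(self.rule_name, self.z_cut)

    def fit(self, normalized: NormalizedMatrix, meta: pd.DataFrame):
        self._rule()  # validate params
        self.reference_ = compute_reference(normalized, meta, self.reference_group)
        return self

    def predict(
        self, values: pd.DataFrame, below_lod: pd.DataFrame | None = None
    ) -> pd.DataFrame:
        """Vectorized flags for every (protein, sample) cell."""
        ref = self.reference_.table.reindex(values.index)
        evaluable = ref["mean"].notna()
        if below_lod is None:
            below_lod = pd.DataFrame(False, index=values.index, columns=values.columns)
        if self.rule_name == "below_group_min":
            flagged = values.lt(ref["min"], axis=0)
        else:
            z = values.sub(ref["mean"], axis=0).div(ref["sd"], axis=0)
            flagged = z < self.z_cut
        flagged = flagged | below_lod
        out = flagged.astype("object")
        out[values.isna() & ~below_lod] = np.nan
        out.loc[~evaluable] = np.nan
        return out

    def screen_targets(
        self,
        values: pd.DataFrame,
        targets: pd.Series,
        below_lod: pd.DataFrame | None = None,
    ) -> pd.DataFrame:
        """Per-sample report for each sample's causative protein.

        ``targets`` maps sample id -> target protein symbol.
        """
        rows = []
        rule = self._rule()
        for sample, protein in targets.items():
            ref_row = self.reference_.for_protein(protein)
            if protein in values.index:
                value = values.loc[protein, sample]
                lod = bool(below_lod.loc[protein, sample]) if below_lod is not None else False
            else:
                value, lod = np.nan, False
            flag, rationale = flag_sample(value, lod, ref_row, rule)
            rows.append(
                {
                    "sample": sample,
                    "protein": protein,
                    "value": value,
                    "below_lod": lod,
                    "reference_mean": np.nan if ref_row is None else ref_row["mean"],
                    "reference_sd": np.nan if ref_row is None else ref_row["sd"],
                    "reference_min": np.nan if ref_row is None else ref_row["min"],
                    "flag": flag,
                    "rule": rule.rule_name,
                    "rationale": rationale,
                }
            )
        return pd.DataFrame(rows).set_index("sample")


# ---------------------------------------------------------------------------
# phenotype panels
# ---------------------------------------------------------------------------


def panel_score(
    sample_values: pd.Series,
    panel: PhenotypePanel,
    reference: ReferenceStats,
) -> float:
    """Mean z-score of the panel members against the healthy reference.

    Members without a value or without a reference interval are skipped;
    at least one member must be scorable.
    """
    zs = []
    for protein in panel.members:
        row = reference.for_protein(protein)
        if row is None or protein not in sample_values.index:
            continue
        v = sample_values[protein]
        if pd.isna(v) or pd.isna(row["sd"]) or row["sd"] == 0:
            continue
        zs.append((v - row["mean"]) / row["sd"])
    if not zs:
        raise ValidationError(f"no scorable member of panel {panel.panel_name!r}")
    return float(np.mean(zs))


def panel_scores(
    values: pd.DataFrame,
    reference: ReferenceStats,
    panels: dict[str, list[str]] | None = None,
) -> pd.DataFrame:
    """Panel x nothing -> samples x panels table of mean member z-scores."""
    panels = panels or DEFAULT_PANELS
    out = {}
    for name, members in panels.items():
        panel = PhenotypePanel(name, members)
        out[name] = {
            sample: panel_score(values[sample], panel, reference)
            for sample in values.columns
        }
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# cohort structure
# ---------------------------------------------------------------------------


def correlation_matrix(values: pd.DataFrame, samples: list[str] | None = None) -> pd.DataFrame:
    """Pairwise Pearson correlation between sample columns."""
    sub = values if samples is None else values[list(samples)]
    if sub.shape[1] < 2:
        raise ValidationError("need >= 2 samples for a correlation matrix")
    if sub.isna().any().any():
        raise ValidationError("correlation requires a complete matrix")
    sd = sub.std(ddof=0)
    zero = sd.index[sd == 0]
    if len(zero):
        raise ValidationError(f"zero-variance sample(s): {list(zero)}")
    return sub.corr(method="pearson")


def pca_scores(
    zscored: NormalizedMatrix | pd.DataFrame, n_components: int = 2
) -> tuple[pd.DataFrame, np.ndarray]:
    """Per-sample principal-component scores with a deterministic sign.

    Input rows are proteins, columns samples (samples are the observations).
    Components come back ordered by decreasing explained variance; each
    component is flipped so its largest-magnitude protein loading is
    positive.  Returns (scores indexed by sample, explained-variance
    fractions).
    """
    values = zscored.values if isinstance(zscored, NormalizedMatrix) else zscored
    if values.isna().any().any():
        raise ValidationError("PCA requires a complete matrix")
    X = values.to_numpy(dtype=float).T  # samples x proteins
    rank = np.linalg.matrix_rank(X - X.mean(axis=0))
    if n_components > rank:
        raise ValidationError(f"n_components={n_components} exceeds data rank {rank}")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    # deterministic sign convention
    for k in range(n_components):
        loading = pca.components_[k]
        if loading[np.argmax(np.abs(loading))] < 0:
            pca.components_[k] *= -1
            scores[:, k] *= -1
    score_df = pd.DataFrame(
        scores,
        index=values.columns,
        columns=[f"PC{k + 1}" for k in range(n_components)],
    )
    return score_df, pca.explained_variance_ratio_


def hierarchical_cluster(
    values: pd.DataFrame,
    axis: str = "sample",
    distance: str = "correlation",
    linkage: str = "average",
) -> tuple[np.ndarray, list[str]]:
    """Agglomerative clustering of samples (columns) or proteins (rows).

    Returns the scipy linkage matrix and the leaf order (labels).  Ties
    break by input order (scipy's deterministic behaviour for equal
    distances in the 'average'/'complete' schemes).
    """
    if distance not in ("correlation", "euclidean"):
        raise ValidationError("distance must be 'correlation' or 'euclidean'")
    if linkage not in ("average", "complete"):
        raise ValidationError("linkage must be 'average' or 'complete'")
    data = values.T if axis == "sample" else values
    labels = list(data.index)
    if len(labels) < 2:
        raise ValidationError("need >= 2 items to cluster")
    dist = pdist(data.to_numpy(dtype=float), metric=distance)
    # guard tiny negative round-off in correlation distances
    dist = np.clip(dist, 0.0, None)
    Z = hierarchy.linkage(dist, method=linkage)
    order = [labels[i] for i in hierarchy.leaves_list(Z)]
    return Z, order


def cut_clusters(Z: np.ndarray, labels: list[str], k: int) -> dict[str, int]:
    """Partition into k flat clusters; returns label -> cluster id."""
    assign = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    return dict(zip(labels, (int(a) for a in assign)))
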