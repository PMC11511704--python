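"""Preprocessing of raw DBS quantification matrices.

The chain mirrors the standard DIA proteomics workflow for this kind of
screen: keep proteins with enough peptide evidence that are quantified in
every reference sample, express each protein relative to beta-actin in the
same sample (%beta-actin), move to log2, fill censored/missing cells by
downshifted-Gaussian imputation (the usual treatment for
missing-not-at-random censoring at the detection limit), then z-score for
clustering/PCA.

Every step is a scikit-learn style transformer so chains compose with
``sklearn.pipeline``; the module-level functions are thin wrappers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .matrix import AbundanceMatrix, NormalizedMatrix, ValidationError

ACTB = "ACTB"


@dataclass
class ImputeParams:
    """Downshift-imputation parameters.

    width
        SD of the imputation Gaussian as a fraction of the observed SD
        (default 0.3).
    downshift
        Shift of the imputation Gaussian below the observed mean, in
        multiples of the observed SD (default 2.4).
    """

    width: float = 0.3
    downshift: float = 2.4
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValidationError("imputation width must be > 0")
        if self.downshift < 0:
            raise ValidationError("imputation downshift must be >= 0")


class EvidenceFilter(BaseEstimator, TransformerMixin):
    """Keep proteins with >= ``min_peptides`` identified peptides that are
    quantified (non-missing) in every sample of ``require_complete_in``.

    Idempotent; protein order is preserved.
    """

    def __init__(self, min_peptides: int = 2, require_complete_in: list[str] | None = None):
        self.min_peptides = min_peptides
        self.require_complete_in = require_complete_in

    def fit(self, X: AbundanceMatrix, y=None):
        subset = self.require_complete_in
        if subset is not None:
            if len(subset) == 0:
                raise ValidationError("require_complete_in must not be empty")
            unknown = set(subset) - set(X.samples)
            if unknown:
                raise ValidationError(f"unknown sample(s) {sorted(unknown)}")
        keep = X.peptide_counts >= self.min_peptides
        if subset is not None:
            complete = X.intensities[list(subset)].notna().all(axis=1)
            keep &= complete
        self.kept_proteins_ = list(X.proteins[keep])
        return self

    def transform(self, X: AbundanceMatrix) -> AbundanceMatrix:
        kept = [p for p in self.kept_proteins_ if p in X.proteins]
        return X.subset_proteins(kept)


class ActinNormalizer(BaseEstimator, TransformerMixin):
    """Express every protein as a percentage of beta-actin in the same
    sample: value = 100 * intensity / ACTB intensity.

    The anchor row must be present and quantified in every sample; after
    normalization it equals 100 everywhere.  Missing/censored cells
    propagate unchanged.
    """

    def __init__(self, actb_protein: str = ACTB):
        self.actb_protein = actb_protein

    def fit(self, X: AbundanceMatrix, y=None):
        return self

    def transform(self, X: AbundanceMatrix) -> NormalizedMatrix:
        if self.actb_protein not in X.proteins:
            raise ValidationError(f"anchor protein {self.actb_protein!r} not in matrix")
        actb = X.intensities.loc[self.actb_protein]
        bad = actb.index[actb.isna() | (actb <= 0)]
        if len(bad):
            raise ValidationError(
                f"anchor protein {self.actb_protein!r} missing or non-positive "
                f"in sample(s) {list(bad)}"
            )
        values = 100.0 * X.intensities.div(actb, axis=1)
        return NormalizedMatrix(values, "percent_actb", X.below_lod.copy())


class Log2Transformer(BaseEstimator, TransformerMixin):
    """log2 of %beta-actin values; zeros must have been censored upstream."""

    def fit(self, X: NormalizedMatrix, y=None):
        return self

    def transform(self, X: NormalizedMatrix) -> NormalizedMatrix:
        if X.transform_state != "percent_actb":
            raise ValidationError(
                f"log2 expects percent_actb input, got {X.transform_state!r}"
            )
        vals = X.values.to_numpy(dtype=float)
        if np.any(vals[np.isfinite(vals)] <= 0):
            raise ValidationError(
                "non-positive value encountered; censor zeros before log2"
            )
        return X.with_values(np.log2(X.values), "log2")


class DownshiftImputer(BaseEstimator, TransformerMixin):
    """Fill missing/censored cells with draws from a downshifted Gaussian.

    For each sample column with observed mean m and sample SD s, absent
    cells are drawn from Normal(m - downshift*s, (width*s)^2).  This places
    imputed values in the low tail of the observed distribution, the
    standard assumption for intensities censored at the detection limit.
    Observed cells are never altered.  With ``per_column=False`` the moments
    come from the whole matrix instead.
    """

    def __init__(
        self,
        width: float = 0.3,
        downshift: float = 2.4,
        random_state: int | None = None,
        per_column: bool = True,
    ):
        self.width = width
        self.downshift = downshift
        self.random_state = random_state
        self.per_column = per_column

    def fit(self, X: NormalizedMatrix, y=None):
        ImputeParams(self.width, self.downshift)  # parameter validation
        return self

    def transform(self, X: NormalizedMatrix) -> NormalizedMatrix:
        if X.transform_state != "log2":
            raise ValidationError(
                f"imputation expects log2 input, got {X.transform_state!r}"
            )
        self.fit(X)
        rng = np.random.default_rng(self.random_state)
        vals = X.values.to_numpy(dtype=float).copy()
        absent = np.isnan(vals)
        if not absent.any():
            return X.with_values(X.values.copy(), "log2")
        if self.per_column:
            n_obs = (~absent).sum(axis=0)
            if (n_obs < 3).any():
                bad = X.samples[n_obs < 3]
                raise ValidationError(
                    f"sample(s) {list(bad)} have fewer than 3 observed values"
                )
            m = np.nanmean(vals, axis=0)
            s = np.nanstd(vals, axis=0, ddof=1)
            loc = m - self.downshift * s
            scale = self.width * s
            for j in range(vals.shape[1]):
                idx = absent[:, j]
                if idx.any():
                    vals[idx, j] = rng.normal(loc[j], scale[j], size=idx.sum())
        else:
            if (~absent).sum() < 3:
                raise ValidationError("fewer than 3 observed values in matrix")
            m = np.nanmean(vals)
            s = np.nanstd(vals, ddof=1)
            vals[absent] = rng.normal(
                m - self.downshift * s, self.width * s, size=absent.sum()
            )
        out = pd.DataFrame(vals, index=X.proteins, columns=X.samples)
        # imputed cells are numeric now; clear the censoring mask
        return NormalizedMatrix(out, "log2")


class ZScoreScaler(BaseEstimator, TransformerMixin):
    """Center/scale to mean 0, SD 1 along proteins (rows) or samples
    (columns).  Sample SD (ddof=1) by default; zero-variance rows/columns
    are a hard error."""

    def __init__(self, axis: str = "protein", ddof: int = 1):
        self.axis = axis
        self.ddof = ddof

    def fit(self, X: NormalizedMatrix, y=None):
        if self.axis not in ("protein", "sample"):
            raise ValidationError("axis must be 'protein' or 'sample'")
        return self

    def transform(self, X: NormalizedMatrix) -> NormalizedMatrix:
        self.fit(X)
        if X.values.isna().any().any():
            raise ValidationError("z-scoring requires a complete matrix; impute first")
        pandas_axis = 1 if self.axis == "protein" else 0
        mean = X.values.mean(axis=pandas_axis)
        sd = X.values.std(axis=pandas_axis, ddof=self.ddof)
        zero = sd.index[sd == 0]
        if len(zero):
            raise ValidationError(
                f"zero-variance {self.axis}(s) cannot be z-scored: {list(zero[:5])}"
            )
        z = X.values.sub(mean, axis=1 - pandas_axis).div(sd, axis=1 - pandas_axis)
        return X.with_values(z, "zscore")


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------


def filter_by_evidence(
    matrix: AbundanceMatrix,
    min_peptides: int = 2,
    require_complete_in: list[str] | None = None,
) -> AbundanceMatrix:
    f = EvidenceFilter(min_peptides, require_complete_in)
    return f.fit(matrix).transform(matrix)


def normalize_actb(matrix: AbundanceMatrix, actb_protein: str = ACTB) -> NormalizedMatrix:
    return ActinNormalizer(actb_protein).fit(matrix).transform(matrix)


def log2_transform(normalized: NormalizedMatrix) -> NormalizedMatrix:
    return Log2Transformer().fit(normalized).transform(normalized)


def impute_downshift(
    log_matrix: NormalizedMatrix,
    params: ImputeParams | None = None,
    per_column: bool = True,
) -> NormalizedMatrix:
    params = params or ImputeParams()
    imputer = DownshiftImputer(params.width, params.downshift, params.seed, per_column)
    return imputer.fit(log_matrix).transform(log_matrix)


def zscore(matrix: NormalizedMatrix, axis: str = "protein", ddof: int = 1) -> NormalizedMatrix:
    return ZScoreScaler(axis, ddof).fit(matrix).transform(matrix)
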