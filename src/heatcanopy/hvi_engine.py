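"""Heat Vulnerability Index construction by rotated principal components.

The HVI summarizes tract-level susceptibility to heat-related morbidity in a
single integer. The pipeline:

1. standardize the schema variables across the cohort (mean 0, SD 1,
   sample-SD convention);
2. principal components of the correlation matrix, retaining components by
   the Kaiser criterion (eigenvalue > 1) or a fixed k;
3. varimax rotation of the retained loadings for interpretability;
4. orient each rotated component so that its summed loading over the
   vulnerability-increasing variables is non-negative — high scores then
   always mean high vulnerability;
5. per-tract component scores as the loading-weighted sum of standardized
   variables;
6. re-standardize each component score across the cohort (mean 0, SD 1);
7. bin each z-score into categories 1-6 by its distance in SDs from the
   cohort mean (below -2 SD -> 1, above +2 SD -> 6);
8. sum the categorical scores into the overall HVI (range k..6k).

Everything here is deterministic: identical input and config give identical
output bit for bit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_schema import (
    Direction,
    TractVariableTable,
    ValidationError,
    SchemaError,
    VariableSchema,
)

logger = logging.getLogger("heatcanopy")

#: Number of categorical vulnerability bands.
N_BANDS = 6
#: Interior bin edges in z units; the outer bands are open-ended.
BIN_EDGES = (-2.0, -1.0, 0.0, 1.0, 2.0)


class RetentionError(ValueError):
    """No component satisfies the retention criterion."""


# ---------------------------------------------------------------------------
# Standardization
# ---------------------------------------------------------------------------

def standardize_variables(
    table: TractVariableTable | pd.DataFrame,
) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Standardize each variable to mean 0, SD 1 across the cohort.

    Uses the sample-SD convention (n-1 denominator). Returns the
    standardized frame plus fitted means and SDs for reuse on new data.

    Raises
    ------
    ValidationError
        If fewer than 3 tracts, or any variable is constant.
    """
    df = table.data if isinstance(table, TractVariableTable) else table
    if len(df) < 3:
        raise ValidationError(f"need at least 3 tracts to standardize, got {len(df)}")
    means = df.mean(axis=0)
    sds = df.std(axis=0, ddof=1)
    zero = sds.index[sds == 0]
    if len(zero):
        raise ValidationError(f"zero-variance variable(s): {list(zero)}")
    z = (df - means) / sds
    return z, means, sds


def standardize_scores(raw: pd.DataFrame) -> pd.DataFrame:
    """Standardize raw component scores to cohort mean 0, SD 1 per component."""
    if len(raw) < 3:
        raise ValidationError(f"need at least 3 tracts, got {len(raw)}")
    sds = raw.std(axis=0, ddof=1)
    zero = sds.index[sds == 0]
    if len(zero):
        raise ValidationError(f"zero-variance component(s): {list(zero)}")
    return (raw - raw.mean(axis=0)) / sds


# ---------------------------------------------------------------------------
# Rotation
# ---------------------------------------------------------------------------

def varimax(loadings: np.ndarray, max_iter: int = 500, tol: float = 1e-10) -> tuple[np.ndarray, np.ndarray]:
    """Varimax rotation of a loading matrix (variables x components).

    Iterative SVD algorithm maximizing the variance of squared loadings
    within each component under an orthogonal rotation.  Returns the rotated
    loadings and the rotation matrix R with ``rotated = loadings @ R``.
    Orthogonality of R guarantees per-variable communalities (row sums of
    squared loadings) are preserved exactly.
    """
    p, k = loadings.shape
    if k == 1:
        return loadings.copy(), np.eye(1)
    R = np.eye(k)
    criterion = 0.0
    for _ in range(max_iter):
        rotated = loadings @ R
        u, s, vt = np.linalg.svd(
            loadings.T
            @ (rotated**3 - rotated @ np.diag((rotated**2).sum(axis=0)) / p)
        )
        R = u @ vt
        new_criterion = s.sum()
        if new_criterion <= criterion * (1.0 + tol):
            break
        criterion = new_criterion
    return loadings @ R, R


def tucker_congruence(a: np.ndarray, b: np.ndarray) -> float:
    """Tucker congruence (cosine similarity) between two loading vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    denom = np.sqrt((a**2).sum() * (b**2).sum())
    if denom == 0:
        raise ValidationError("zero loading vector in congruence computation")
    return float((a * b).sum() / denom)


# ---------------------------------------------------------------------------
# Weighting model
# ---------------------------------------------------------------------------

@dataclass
class WeightingModel:
    """Retained, rotated, oriented component loadings used as HVI weights.

    ``loadings`` is variables x retained-components, already rotated and
    sign-oriented.  ``eigenvalues`` are the pre-rotation correlation-matrix
    eigenvalues of the retained components, non-increasing.
    """

    variables: list[str]
    loadings: np.ndarray
    eigenvalues: np.ndarray
    variable_means: pd.Series
    variable_sds: pd.Series
    orientation_signs: np.ndarray
    component_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        k = self.loadings.shape[1]
        if not (1 <= k <= len(self.variables)):
            raise ValidationError(f"retained components k={k} out of range")
        if np.any(np.diff(self.eigenvalues) > 1e-12):
            raise ValidationError("eigenvalues must be non-increasing")
        if (self.variable_sds <= 0).any():
            raise ValidationError("variable SDs must be positive")
        if not self.component_labels:
            self.component_labels = [f"component_{i + 1}" for i in range(k)]

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    def to_frame(self) -> pd.DataFrame:
        """Loadings, eigenvalues and signs as a tidy exportable frame."""
        df = pd.DataFrame(self.loadings, index=self.variables, columns=self.component_labels)
        df.loc["__eigenvalue__"] = self.eigenvalues
        df.loc["__orientation_sign__"] = self.orientation_signs
        return df


def fit_weighting_model(
    z: pd.DataFrame,
    schema: VariableSchema,
    retention: str | int = "kaiser",
    *,
    loading_threshold: float = 0.0,
) -> WeightingModel:
    """Fit the rotated-PCA weighting model on a standardized variable table.

    Parameters
    ----------
    z
        Standardized tract-by-variable frame (columns in schema order).
    retention
        ``"kaiser"`` retains components with correlation-matrix eigenvalue
        greater than 1; an integer retains exactly that many leading
        components (the escape hatch for interpretability-based retention).
    loading_threshold
        Absolute-loading salience cutoff; rotated loadings smaller in
        magnitude are zeroed before use as weights. Default 0 keeps the full
        loading vectors.
    """
    if list(z.columns) != schema.names:
        raise SchemaError("standardized table columns do not match schema order")
    X = z.to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValidationError("non-finite values in standardized table")
    n, p = X.shape
    if n <= p:
        logger.warning("cohort has %d tracts for %d variables; PCA may be unstable", n, p)

    corr = np.corrcoef(X, rowvar=False)
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]

    if retention == "kaiser":
        k = int((eigvals > 1.0).sum())
        if k == 0:
            raise RetentionError(
                "no eigenvalue exceeds 1; pass a fixed integer retention instead"
            )
    else:
        k = int(retention)
        if not (1 <= k <= p):
            raise RetentionError(f"fixed retention k={k} outside 1..{p}")
    logger.info("retained %d of %d components (eigenvalues %s)", k, p,
                np.round(eigvals[:k], 3))

    # Component loadings: eigenvectors scaled by sqrt(eigenvalue), then varimax.
    loadings = eigvecs[:, :k] * np.sqrt(eigvals[:k])
    rotated, _ = varimax(loadings)

    inc_mask = np.array([schema.direction(v) is Direction.INCREASING for v in schema.names])
    signs = np.ones(k)
    for c in range(k):
        if rotated[inc_mask, c].sum() < 0:
            signs[c] = -1.0
    oriented = rotated * signs

    if loading_threshold > 0:
        oriented = np.where(np.abs(oriented) >= loading_threshold, oriented, 0.0)

    return WeightingModel(
        variables=list(schema.names),
        loadings=oriented,
        eigenvalues=eigvals[:k],
        variable_means=z.mean(axis=0),
        variable_sds=z.std(axis=0, ddof=1),
        orientation_signs=signs,
    )


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

def component_scores(z: pd.DataFrame, model: WeightingModel) -> pd.DataFrame:
    """Raw component score per tract: the loading-weighted sum of z-values.

    score(t, c) = sum_v loading(v, c) * z(t, v); orientation signs are
    already folded into the model's loadings.
    """
    if list(z.columns) != model.variables:
        raise SchemaError("table columns do not match model variables")
    raw = z.to_numpy(dtype=float) @ model.loadings
    return pd.DataFrame(raw, index=z.index, columns=model.component_labels)


def component_scores_standardize_each(z: pd.DataFrame, model: WeightingModel) -> pd.DataFrame:
    """Alternative scoring: standardize each weighted variable, then sum.

    Re-standardizing loading * z reduces every non-zero weight to its sign,
    so this reading weights variables equally within a component. Exposed as
    a config switch; the weighted-sum reading is the default.
    """
    if list(z.columns) != model.variables:
        raise SchemaError("table columns do not match model variables")
    cols = {}
    for c, label in enumerate(model.component_labels):
        acc = np.zeros(len(z))
        for v, var in enumerate(model.variables):
            w = model.loadings[v, c]
            if w == 0:
                continue
            weighted = w * z[var].to_numpy()
            sd = weighted.std(ddof=1)
            acc += (weighted - weighted.mean()) / sd
        cols[label] = acc
    return pd.DataFrame(cols, index=z.index)


def categorize_score(z: float) -> int:
    """Bin a standardized component score into vulnerability categories 1-6.

    Half-open, lower-closed bands in SD units from the cohort mean:
    z < -2 -> 1; [-2,-1) -> 2; [-1,0) -> 3; [0,1) -> 4; [1,2) -> 5; z >= 2 -> 6.
    The least vulnerable band (more than 2 SD below the mean) scores 1 and
    the most vulnerable (more than 2 SD above) scores 6.
    """
    if not np.isfinite(z):
        raise ValidationError(f"cannot categorize non-finite z-score {z!r}")
    band = 1
    for edge in BIN_EDGES:
        if z >= edge:
            band += 1
    return band


def categorize_scores(z: pd.DataFrame) -> pd.DataFrame:
    """Vectorized 1-6 binning of a z-score frame (same rule as categorize_score)."""
    if not np.isfinite(z.to_numpy()).all():
        raise ValidationError("non-finite z-scores")
    binned = np.digitize(z.to_numpy(), BIN_EDGES, right=False) + 1
    return pd.DataFrame(binned, index=z.index, columns=z.columns)


def total_hvi(categorical: pd.DataFrame) -> pd.Series:
    """Sum the per-component categorical scores into the overall HVI.

    With k retained components the HVI ranges from k (least vulnerable
    everywhere) to 6k (most vulnerable everywhere).
    """
    arr = categorical.to_numpy()
    if ((arr < 1) | (arr > N_BANDS)).any():
        raise ValidationError("categorical scores must lie in 1..6")
    return categorical.sum(axis=1).astype(int).rename("hvi")


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

@dataclass
class HviResult:
    """All per-tract artifacts of one HVI run, plus the fitted model.

    ``scores`` is indexed by tract and carries raw_, z_ and cat_ columns per
    component plus the summed integer ``hvi``.
    """

    model: WeightingModel
    raw_scores: pd.DataFrame
    z_scores: pd.DataFrame
    categorical_scores: pd.DataFrame
    hvi: pd.Series

    @property
    def scores(self) -> pd.DataFrame:
        out = pd.concat(
            [
                self.raw_scores.add_prefix("raw_"),
                self.z_scores.add_prefix("z_"),
                self.categorical_scores.add_prefix("cat_"),
            ],
            axis=1,
        )
        out["hvi"] = self.hvi
        return out


def run_hvi_pipeline(
    table: TractVariableTable,
    retention: str | int = "kaiser",
    *,
    loading_threshold: float = 0.0,
    scoring: str = "weighted_sum",
) -> HviResult:
    """Run the full HVI pipeline on a validated tract table.

    ``scoring`` selects how component scores are formed before cohort
    standardization: ``"weighted_sum"`` (default; loading-weighted sum of
    standardized variables) or ``"standardize_each"`` (standardize each
    weighted variable, then sum).
    """
    z, means, sds = standardize_variables(table)
    model = fit_weighting_model(
        z, table.schema, retention, loading_threshold=loading_threshold
    )
    model.variable_means = means
    model.variable_sds = sds
    if scoring == "weighted_sum":
        raw = component_scores(z, model)
    elif scoring == "standardize_each":
        raw = component_scores_standardize_each(z, model)
    else:
        raise ValueError(f"unknown scoring mode {scoring!r}")
    zscores = standardize_scores(raw)
    cat = categorize_scores(zscores)
    hvi = total_hvi(cat)
    logger.info(
        "HVI over %d tracts: min %d, median %.1f, max %d",
        len(hvi), hvi.min(), hvi.median(), hvi.max(),
    )
    return HviResult(model=model, raw_scores=raw, z_scores=zscores,
                     categorical_scores=cat, hvi=hvi)
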