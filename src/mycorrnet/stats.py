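"""Cross-forest comparison of network properties: ANOVA and correlation PCA.

One row per (forest, category) carries the descriptive indices and the
relative (null-standardized) indices.  For each relative index an ANOVA
linear model partitions variation among the number of plant species/taxa, the
number of fungal OTUs, connectance, locality (forest site, a factor) and
network category (a factor), with sequential (type-I) sums of squares in that
term order and a Bonferroni correction over the terms of each model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .errors import ValidationError

PROPERTY_COLUMNS = [
    "forest_id",
    "category",
    "n_plants",
    "n_otus",
    "fungus_plant_ratio",
    "connectance",
    "rel_h2prime",
    "rel_wnodf",
    "rel_cscore",
]

#: Model terms in their fitting order: diversity covariates first, then the
#: locality and category factors.
_TERM_NAMES = ["n_plants", "n_otus", "connectance", "forest_id", "category"]

PCA_VARIABLES = [
    "rel_h2prime",
    "rel_wnodf",
    "rel_cscore",
    "n_plants",
    "n_otus",
    "fungus_plant_ratio",
    "connectance",
]


@dataclass
class AnovaTerm:
    name: str
    df: int
    sum_sq: float
    F: float
    p: float
    p_bonferroni: float


@dataclass
class AnovaTable:
    response: str
    terms: list[AnovaTerm]
    residual_df: int
    residual_sum_sq: float
    ss_type: str

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "term": t.name,
                    "df": t.df,
                    "sum_sq": t.sum_sq,
                    "F": t.F,
                    "p": t.p,
                    "p_bonferroni": t.p_bonferroni,
                }
                for t in self.terms
            ]
        )


@dataclass
class PcaResult:
    variables: list[str]
    loadings: np.ndarray  # variable x component
    scores: np.ndarray  # row x component
    explained_variance: np.ndarray  # proportions, sum to 1


def build_property_table(
    results: dict[tuple[str, str], dict[str, float | None]]
) -> pd.DataFrame:
    """Assemble one row per (forest, category) from per-network result dicts.

    Each value dict provides the PROPERTY_COLUMNS fields (minus the keys);
    missing/undefined indices are stored as NaN.  Duplicate keys are refused.
    """
    seen = set()
    rows = []
    for (forest_id, category), vals in results.items():
        key = (forest_id, category)
        if key in seen:
            raise ValidationError(f"duplicate (forest, category) key {key}")
        seen.add(key)
        row = {"forest_id": forest_id, "category": category}
        for col in PROPERTY_COLUMNS[2:]:
            v = vals.get(col)
            row[col] = np.nan if v is None else float(v)
        rows.append(row)
    df = pd.DataFrame(rows, columns=PROPERTY_COLUMNS)
    return df.sort_values(["forest_id", "category"], ignore_index=True)


def _check_rank(frame: pd.DataFrame, response: str) -> None:
    for factor in ("forest_id", "category"):
        counts = frame[factor].value_counts()
        thin = counts[counts < 2]
        if len(frame[factor].unique()) > 1 and not thin.empty:
            # A level with a single row cannot be separated from the residual
            # once the other terms are in the model.
            raise ValidationError(
                f"ANOVA for {response}: factor {factor} level(s) "
                f"{list(thin.index)} have fewer than 2 rows after dropping "
                "missing values"
            )


def _design_blocks(frame: pd.DataFrame) -> list[np.ndarray]:
    """One design-matrix block per model term, in the fixed term order."""
    blocks = []
    for col in ("n_plants", "n_otus", "connectance"):
        blocks.append(frame[col].to_numpy(np.float64)[:, None])
    for factor in ("forest_id", "category"):
        dummies = pd.get_dummies(
            frame[factor].astype(str), drop_first=True, dtype=np.float64
        )
        blocks.append(dummies.to_numpy())
    return blocks


def anova_network_properties(
    pt: pd.DataFrame, response: str, ss_type: str = "sequential"
) -> AnovaTable:
    """ANOVA of one relative index on diversity covariates, locality and category.

    Rows with any missing model variable are dropped listwise.  ``ss_type``
    selects sequential (type-I, default; terms entered in the fixed order
    above) or marginal (type-II, drop-one) sums of squares; the degrees of
    freedom are identical under both.
    """
    if response not in ("rel_h2prime", "rel_wnodf", "rel_cscore"):
        raise ValidationError(f"unsupported response {response!r}")
    if ss_type not in ("sequential", "marginal"):
        raise ValidationError(f"unknown ss_type {ss_type!r}")
    cols = ["n_plants", "n_otus", "connectance", "forest_id", "category", response]
    frame = pt[cols].dropna()
    n_terms = len(_TERM_NAMES)
    if len(frame) < n_terms + 2:
        raise ValidationError(f"ANOVA for {response}: only {len(frame)} complete rows")
    _check_rank(frame, response)
    y = frame[response].to_numpy(np.float64)
    blocks = _design_blocks(frame)
    intercept = np.ones((len(frame), 1))
    full = np.hstack([intercept] + blocks)
    if np.linalg.matrix_rank(full) < full.shape[1]:
        raise ValidationError(f"ANOVA for {response}: rank-deficient design")

    def rss(x: np.ndarray) -> float:
        return float(sm.OLS(y, x).fit().ssr)

    rss_full = rss(full)
    df_resid = len(frame) - full.shape[1]
    if df_resid < 1:
        raise ValidationError(f"ANOVA for {response}: no residual degrees of freedom")
    ms_resid = rss_full / df_resid
    term_ss = []
    if ss_type == "sequential":
        x = intercept
        prev = rss(x)
        for b in blocks:
            x = np.hstack([x, b])
            cur = rss(x)
            term_ss.append(prev - cur)
            prev = cur
    else:
        for k in range(len(blocks)):
            reduced = np.hstack([intercept] + [b for i, b in enumerate(blocks) if i != k])
            term_ss.append(rss(reduced) - rss_full)
    terms = []
    for name, b, ss in zip(_TERM_NAMES, blocks, term_ss):
        df = b.shape[1]
        f_stat = (ss / df) / ms_resid
        p = float(sps.f.sf(f_stat, df, df_resid))
        terms.append(
            AnovaTerm(
                name=name,
                df=df,
                sum_sq=float(ss),
                F=float(f_stat),
                p=p,
                p_bonferroni=min(1.0, p * n_terms),
            )
        )
    return AnovaTable(
        response=response,
        terms=terms,
        residual_df=df_resid,
        residual_sum_sq=rss_full,
        ss_type=ss_type,
    )


def pca_network_properties(pt: pd.DataFrame) -> PcaResult:
    """Correlation-matrix PCA of the seven network-property variables.

    Rows with any missing variable are dropped; variables are standardized to
    zero mean and unit variance, so components are eigenvectors of the
    correlation matrix.  Components are ordered by decreasing eigenvalue and
    signed so the largest-magnitude loading of each is positive.
    """
    frame = pt[PCA_VARIABLES].dropna()
    if len(frame) < 3:
        raise ValidationError(f"PCA needs >= 3 complete rows, got {len(frame)}")
    x = frame.to_numpy(dtype=np.float64)
    sd = x.std(axis=0, ddof=1)
    constant = np.flatnonzero(sd == 0)
    if constant.size:
        raise ValidationError(
            f"PCA: constant variable(s) {[PCA_VARIABLES[i] for i in constant]}"
        )
    z = (x - x.mean(axis=0)) / sd
    corr = (z.T @ z) / (len(frame) - 1)
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    loadings = eigvecs[:, order]
    for k in range(loadings.shape[1]):
        top = np.argmax(np.abs(loadings[:, k]))
        if loadings[top, k] < 0:
            loadings[:, k] = -loadings[:, k]
    scores = z @ loadings
    explained = eigvals / eigvals.sum()
    return PcaResult(
        variables=list(PCA_VARIABLES),
        loadings=loadings,
        scores=scores,
        explained_variance=explained,
    )
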