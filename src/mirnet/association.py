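"""The rank-based miRNA-phenotype association screen.

The screen correlates per-subject-normalized miRNA expression with every
subject variable — demographics, global cognition, five cognitive-domain
composites, the individual test battery, and ordinal neuropathology —
using tie-corrected Spearman rank correlation (point-biserial Pearson R
for chromosomal sex).  Associations with uncorrected two-sided p < alpha
survive, after removing miRNAs present in fewer than ``min_present``
subjects.  All subjects enter every correlation: zero counts are ranked,
tied, at the bottom, so ranks always span the whole cohort; sparsity is
handled by the presence filter alone (a pairwise-complete mode for
*phenotype* missingness is on by default and logs the n actually used).

The public surface is statsmodels-shaped: build a
:class:`MiRNAPhenotypeModel` from an expression matrix and a cohort,
``fit()`` it, and read the :class:`MiRNAPhenotypeResults`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datamodel import (
    DOMAIN_HUB_LABELS,
    AnalysisConfig,
    CohortTable,
    DomainMap,
    ExpressionMatrix,
    RECORD_COLUMNS,
    ValidationError,
    default_domain_map,
)

logger = logging.getLogger(__name__)

__all__ = [
    "RankedVector",
    "AssociationSummary",
    "rank_with_ties",
    "normalize_per_subject",
    "presence_filter",
    "composite_domain_score",
    "spearman",
    "point_biserial",
    "critical_rho",
    "phenotype_frame",
    "screen",
    "summarize",
    "summarize_all",
    "MiRNAPhenotypeModel",
    "MiRNAPhenotypeResults",
]

_P_FLOOR = np.finfo(float).tiny


@dataclass(frozen=True)
class RankedVector:
    """Ascending ranks (1 = lowest) with ties at the average rank."""

    values: np.ndarray
    tie_groups: tuple[int, ...]

    @property
    def n(self) -> int:
        return len(self.values)


def rank_with_ties(x) -> RankedVector:
    """Rank a vector ascending, assigning tied values their mean rank."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValidationError("rank_with_ties needs a 1-D vector of length >= 2")
    if not np.isfinite(x).all():
        raise ValidationError("rank_with_ties: non-finite input")
    ranks = stats.rankdata(x, method="average")
    _, counts = np.unique(x, return_counts=True)
    ties = tuple(sorted(int(c) for c in counts if c > 1))
    return RankedVector(values=ranks, tie_groups=ties)


def normalize_per_subject(m: ExpressionMatrix) -> ExpressionMatrix:
    """Divide each subject column by its total miRNA count."""
    if m.normalized:
        return m
    totals = m.counts.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValidationError(
            f"zero total expression for subject(s): {zero.index.tolist()}"
        )
    return ExpressionMatrix(m.counts / totals, normalized=True)


def presence_filter(m: ExpressionMatrix, min_present: int) -> ExpressionMatrix:
    """Keep miRNAs with a nonzero count in at least ``min_present`` subjects."""
    keep = m.n_present >= min_present
    return ExpressionMatrix(m.counts.loc[keep], normalized=m.normalized)


def composite_domain_score(
    cohort: CohortTable, dm: DomainMap, domain: str
) -> pd.Series:
    """Per-subject composite: mean of per-test z-scores over the domain.

    z-scores are computed across subjects within each test (sample SD);
    a subject's composite averages its non-missing mapped tests.
    """
    if domain not in dm.domains:
        raise KeyError(domain)
    sub = cohort.df[dm.domains[domain]].astype(float)
    z = (sub - sub.mean()) / sub.std(ddof=1)
    all_missing = z.isna().all(axis=1)
    if all_missing.any():
        ids = cohort.df.loc[all_missing, "subject_id"].tolist()
        raise ValidationError(
            f"subject(s) with no scores in domain {domain!r}: {ids}"
        )
    out = z.mean(axis=1)
    out.name = domain
    return out


def _t_pvalue(rho: np.ndarray, n) -> np.ndarray:
    """Two-sided p via t = rho*sqrt((n-2)/(1-rho^2)) on n-2 df."""
    rho = np.asarray(rho, dtype=float)
    n = np.asarray(n, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
        p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    p = np.where(np.isclose(np.abs(rho), 1.0), _P_FLOOR, p)
    return np.maximum(p, _P_FLOOR)


def spearman(x, y) -> tuple[float, float, int]:
    """Tie-corrected Spearman rho with the t-approximation p-value.

    rho is the Pearson correlation of mean-rank-assigned ranks; the
    two-sided p uses t = rho*sqrt((n-2)/(1-rho^2)) on n-2 degrees of
    freedom.  |rho| = 1 reports p at the machine floor, never 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 4:
        raise ValidationError("spearman needs equal-length vectors, n >= 4")
    rx = rank_with_ties(x).values
    ry = rank_with_ties(y).values
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise ValidationError("spearman undefined: zero variance after ranking")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    rho = float(np.clip(rho, -1.0, 1.0))
    return rho, float(_t_pvalue(rho, len(x))), len(x)


def point_biserial(b, y) -> tuple[float, float, int]:
    """Point-biserial correlation: Pearson R of 0/1-coded b with y."""
    b = np.asarray(b, dtype=float)
    y = np.asarray(y, dtype=float)
    if b.shape != y.shape or b.ndim != 1 or len(b) < 4:
        raise ValidationError("point_biserial needs equal-length vectors, n >= 4")
    if len(np.unique(b)) < 2:
        raise ValidationError("point_biserial: binary vector has one level")
    if np.ptp(y) == 0:
        raise ValidationError("point_biserial undefined: y has zero variance")
    r = float(np.clip(np.corrcoef(b, y)[0, 1], -1.0, 1.0))
    return r, float(_t_pvalue(r, len(b))), len(b)


def critical_rho(n: int, alpha: float = 0.05) -> float:
    """Smallest |rho| significant at ``alpha`` under the t approximation.

    Inverts t = rho*sqrt((n-2)/(1-rho^2)) at the two-sided critical t on
    n-2 df; at n = 26, alpha = 0.05 this is ~0.388, the screening bound
    of the default analysis.
    """
    if n < 4:
        raise ValidationError("critical_rho needs n >= 4")
    t = stats.t.ppf(1.0 - alpha / 2.0, n - 2)
    return float(t / np.sqrt(n - 2 + t * t))


def phenotype_frame(cohort: CohortTable, dm: DomainMap) -> pd.DataFrame:
    """Numeric phenotype matrix (subjects x phenotypes) entering the screen.

    Columns: age, educ, sex (0 = male, 1 = female), mmse, glob.cog, the
    five domain composites under their hub labels, the 19 individual
    tests, and ordinal pathology (braak, cerad, niareagan, 6e10, at8)
    encoded so that higher pathology gets a higher rank.
    """
    df = cohort.df
    out = pd.DataFrame(index=df.index)
    out["age"] = df["age_at_death"].astype(float)
    out["educ"] = df["education"].astype(float)
    out["sex"] = cohort.ordinal("sex").astype(float)
    out["mmse"] = df["mmse"].astype(float)
    out["glob.cog"] = df["gcs"].astype(float)
    for domain, label in DOMAIN_HUB_LABELS.items():
        out[label] = composite_domain_score(cohort, dm, domain)
    for t in dm.tests:
        out[t] = df[t].astype(float)
    out["braak"] = cohort.ordinal("braak").astype(float)
    out["cerad"] = cohort.ordinal("cerad").astype(float)
    out["niareagan"] = cohort.ordinal("nia_reagan").astype(float)
    out["6e10"] = df["amyloid_load_6e10"].astype(float)
    out["at8"] = df["tangle_load_at8"].astype(float)
    return out


def _rank_rows(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average", axis=1)


def _corr_rows(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson correlation of each row of x with y; NaN for constant rows."""
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    sx = np.sqrt((xc**2).sum(axis=1))
    sy = float(np.sqrt((yc**2).sum()))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (xc @ yc) / (sx * sy)
    r[sx == 0] = np.nan
    return np.clip(r, -1.0, 1.0)


def screen(
    m: ExpressionMatrix,
    cohort: CohortTable,
    dm: DomainMap | None = None,
    cfg: AnalysisConfig | None = None,
    return_all: bool = False,
) -> pd.DataFrame:
    """Correlate every retained miRNA with every phenotype.

    ``m`` should be normalized and presence-filtered (``fit`` does both).
    Returns the records with p < alpha (and q <= fdr_q when BH mode is
    enabled); ``return_all`` instead returns the full tested set with a
    ``significant`` flag.
    """
    dm = dm or default_domain_map()
    cfg = cfg or AnalysisConfig()
    if list(m.subject_ids) != list(cohort.subject_ids):
        raise ValidationError("expression and cohort subject ids differ")
    pheno = phenotype_frame(cohort, dm)
    expr = m.counts.to_numpy(dtype=float)
    mirnas = np.asarray(m.mirna_ids)

    chunks: list[pd.DataFrame] = []
    for phen in pheno.columns:
        y = pheno[phen].to_numpy(dtype=float)
        mask = np.isfinite(y)
        if cfg.pairwise_complete:
            use = mask
        else:
            if not mask.all():
                logger.warning("phenotype %s has missing values; skipped", phen)
                continue
            use = np.ones_like(mask)
        n_used = int(use.sum())
        if n_used < 4:
            logger.warning("phenotype %s: fewer than 4 subjects; skipped", phen)
            continue
        yy = y[use]
        if np.ptp(yy) == 0:
            logger.warning("phenotype %s has zero variance; skipped", phen)
            continue
        xx = expr[:, use]
        if phen == "sex":
            kind = "point_biserial_r"
            r = _corr_rows(xx, yy)
        else:
            kind = "spearman_rho"
            r = _corr_rows(_rank_rows(xx), stats.rankdata(yy, method="average"))
        ok = np.isfinite(r)
        p = np.full_like(r, np.nan)
        p[ok] = _t_pvalue(r[ok], n_used)
        chunks.append(
            pd.DataFrame(
                {
                    "mirna": mirnas[ok],
                    "phenotype": phen,
                    "statistic_kind": kind,
                    "rho": r[ok],
                    "p": p[ok],
                    "n_used": n_used,
                }
            )
        )
    if not chunks:
        records = pd.DataFrame(columns=RECORD_COLUMNS)
        return records
    records = pd.concat(chunks, ignore_index=True)
    if cfg.fdr_q is not None and len(records):
        records["q"] = multipletests(records["p"], method="fdr_bh")[1]
    else:
        records["q"] = np.nan
    records["sign"] = np.where(records["rho"] > 0, "positive", "negative")
    records["highlight"] = records["p"] < cfg.highlight_alpha
    records["significant"] = records["p"] < cfg.alpha
    if cfg.fdr_q is not None:
        records["significant"] &= records["q"] <= cfg.fdr_q
    records = records[RECORD_COLUMNS + ["significant"]]
    if return_all:
        return records
    return records[records["significant"]].drop(columns="significant").reset_index(
        drop=True
    )


@dataclass(frozen=True)
class AssociationSummary:
    """Per-(phenotype, sign) roll-up of the significant records."""

    phenotype_id: str
    sign: str
    count: int
    median_rho: float | None
    rho_range: tuple[float, float] | None
    highlighted: tuple[str, ...]


def summarize(records: pd.DataFrame, phenotype_id: str, sign: str) -> AssociationSummary:
    """Count, median rho, rho range and highlighted miRNAs for one hub."""
    sub = records[(records["phenotype"] == phenotype_id) & (records["sign"] == sign)]
    if len(sub) == 0:
        return AssociationSummary(phenotype_id, sign, 0, None, None, ())
    rhos = sub["rho"].to_numpy()
    lo, hi = float(rhos.min()), float(rhos.max())
    hl = tuple(sub.loc[sub["highlight"].astype(bool), "mirna"])
    return AssociationSummary(
        phenotype_id, sign, len(sub), float(np.median(rhos)), (lo, hi), hl
    )


def summarize_all(records: pd.DataFrame) -> pd.DataFrame:
    """Summaries for every (phenotype, sign) pair with >= 1 record."""
    rows = []
    for (phen, sign), _ in records.groupby(["phenotype", "sign"], sort=True):
        s = summarize(records, phen, sign)
        rows.append(
            {
                "phenotype": s.phenotype_id,
                "sign": s.sign,
                "count": s.count,
                "median_rho": s.median_rho,
                "rho_min": s.rho_range[0],
                "rho_max": s.rho_range[1],
                "n_highlighted": len(s.highlighted),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "phenotype",
            "sign",
            "count",
            "median_rho",
            "rho_min",
            "rho_max",
            "n_highlighted",
        ],
    )


class MiRNAPhenotypeModel:
    """Rank-correlation screen of a miRNA count matrix against a cohort.

    Parameters
    ----------
    expression : ExpressionMatrix
        Raw (or already normalized) miRNA x subject counts.
    cohort : CohortTable
        Per-subject phenotypes; subject columns must match.
    domain_map : DomainMap, optional
        Test-to-domain mapping (defaults to the 19-test battery).
    config : AnalysisConfig, optional
        alpha, min_present, highlight and FDR settings.

    Examples
    --------
    >>> model = MiRNAPhenotypeModel(expr, cohort)
    >>> res = model.fit()
    >>> res.summaries().head()
    """

    def __init__(
        self,
        expression: ExpressionMatrix,
        cohort: CohortTable,
        domain_map: DomainMap | None = None,
        config: AnalysisConfig | None = None,
    ):
        self.expression = expression
        self.cohort = cohort
        self.domain_map = domain_map or default_domain_map()
        self.config = config or AnalysisConfig()
        if list(expression.subject_ids) != list(cohort.subject_ids):
            raise ValidationError("expression and cohort subject ids differ")

    @classmethod
    def from_files(
        cls,
        counts_path,
        phenotypes_path,
        domain_map: DomainMap | None = None,
        config: AnalysisConfig | None = None,
    ) -> "MiRNAPhenotypeModel":
        from .io import read_counts, read_phenotypes

        dm = domain_map or default_domain_map()
        return cls(read_counts(counts_path), read_phenotypes(phenotypes_path, dm), dm, config)

    def fit(self) -> "MiRNAPhenotypeResults":
        """Normalize, presence-filter and screen; return the results."""
        cfg = self.config
        norm = normalize_per_subject(self.expression)
        kept = presence_filter(norm, cfg.min_present)
        if kept.shape[0] == 0:
            logger.warning(
                "presence filter (min_present=%d) removed every miRNA", cfg.min_present
            )
        records = screen(kept, self.cohort, self.domain_map, cfg, return_all=True)
        return MiRNAPhenotypeResults(self, kept, records)


class MiRNAPhenotypeResults:
    """Fitted screen: association records, summaries and network export."""

    def __init__(self, model: MiRNAPhenotypeModel, filtered: ExpressionMatrix, records_all: pd.DataFrame):
        self.model = model
        self.filtered = filtered
        self.records_all = records_all

    @property
    def config(self) -> AnalysisConfig:
        return self.model.config

    @property
    def records(self) -> pd.DataFrame:
        """Significant records (p < alpha, and q <= fdr_q when enabled)."""
        sig = self.records_all[self.records_all["significant"]]
        return sig.drop(columns="significant").reset_index(drop=True)

    @property
    def n_mirna_tested(self) -> int:
        return self.filtered.shape[0]

    @property
    def n_mirna_significant(self) -> int:
        """Distinct miRNAs significant for at least one phenotype."""
        return self.records["mirna"].nunique()

    def critical_rho(self) -> float:
        return critical_rho(self.model.cohort.n_subjects, self.config.alpha)

    def summaries(self) -> pd.DataFrame:
        return summarize_all(self.records)

    def build_network(self):
        from .network import build_network

        return build_network(self.records)

    def group_tests(self) -> pd.DataFrame:
        from .groupstats import cohort_summary

        return cohort_summary(self.model.cohort)

    def to_csv(self, records_path, summaries_path=None) -> None:
        from .io import write_records

        write_records(self.records, records_path)
        if summaries_path is not None:
            self.summaries().to_csv(summaries_path, index=False, float_format="%.6g")

    def summary(self) -> str:
        """Plain-text overview in the spirit of a statsmodels summary."""
        cfg = self.config
        lines = [
            "miRNA-phenotype rank association screen",
            "=" * 55,
            f"subjects:            {self.model.cohort.n_subjects}",
            f"miRNAs input:        {self.model.expression.shape[0]}",
            f"miRNAs tested:       {self.n_mirna_tested} (present in >= {cfg.min_present} subjects)",
            f"alpha:               {cfg.alpha:g} (|rho| >= {self.critical_rho():.3f} at full n)",
            f"FDR mode:            "
            + (f"BH q <= {cfg.fdr_q:g}" if cfg.fdr_q is not None else "off (uncorrected p)"),
            f"significant records: {len(self.records)}",
            f"significant miRNAs:  {self.n_mirna_significant}",
            "",
        ]
        summ = self.summaries()
        if len(summ):
            lines.append(summ.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
        return "\n".join(lines)
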