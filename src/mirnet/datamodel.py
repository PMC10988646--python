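"""Domain types shared across the pipeline.

The pipeline links per-subject miRNA expression in post-mortem cortex to
demographic, cognitive and neuropathological variables in a small autopsy
cohort.  The types here are thin, validated wrappers around pandas
DataFrames plus small dataclasses for configuration; every reader/writer in
:mod:`mirnet.io` produces or consumes them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "BRAAK_LEVELS",
    "CERAD_LEVELS",
    "NIA_REAGAN_LEVELS",
    "APOE_LEVELS",
    "SEX_LEVELS",
    "INTERACTION_CATEGORIES",
    "INTERACTION_SOURCES",
    "ValidationError",
    "braak_group",
    "DomainMap",
    "CohortTable",
    "ExpressionMatrix",
    "AssociationRecord",
    "AnalysisConfig",
    "InteractionTable",
    "ordinal_code",
]


class ValidationError(ValueError):
    """Raised when an input table violates the domain contracts."""


# Ordinal vocabularies and their numeric encodings.  Encodings are fixed
# once here so that ranks are comparable across every entry point:
# Braak I..VI -> 1..6, CERAD No AD < Possible < Probable < Definite -> 0..3,
# NIA-Reagan Low < Intermediate < High -> 0..2, sex male -> 0 / female -> 1
# (a positive point-biserial R therefore means higher expression in females).
BRAAK_LEVELS = ("I", "II", "III", "IV", "V", "VI")
CERAD_LEVELS = ("No AD", "Possible", "Probable", "Definite")
NIA_REAGAN_LEVELS = ("Low", "Intermediate", "High")
SEX_LEVELS = ("male", "female")
APOE_LEVELS = ("e2/e2", "e2/e3", "e2/e4", "e3/e3", "e3/e4", "e4/e4")

_ORDINAL_CODES = {
    "braak": {lvl: i + 1 for i, lvl in enumerate(BRAAK_LEVELS)},
    "cerad": {lvl: i for i, lvl in enumerate(CERAD_LEVELS)},
    "nia_reagan": {lvl: i for i, lvl in enumerate(NIA_REAGAN_LEVELS)},
    "sex": {lvl: i for i, lvl in enumerate(SEX_LEVELS)},
}

INTERACTION_CATEGORIES = (
    "Amyloid associated",
    "Tau associated",
    "Cytokine",
    "Transcription factor",
)
INTERACTION_SOURCES = ("starmir-like", "tarbase-like")


def ordinal_code(kind: str, value: str) -> int:
    """Numeric encoding of an ordinal level (see module docstring)."""
    try:
        return _ORDINAL_CODES[kind][value]
    except KeyError:
        raise ValidationError(f"unknown {kind} level: {value!r}") from None


def braak_group(braak: str) -> str:
    """Study group derived from Braak stage: I/II -> 'I-II', III, IV, V/VI -> 'V-VI'."""
    if braak not in BRAAK_LEVELS:
        raise ValidationError(f"unknown braak level: {braak!r}")
    if braak in ("I", "II"):
        return "I-II"
    if braak in ("V", "VI"):
        return "V-VI"
    return braak


@dataclass(frozen=True)
class DomainMap:
    """Maps each cognitive domain to its neuropsychological tests.

    ``domains`` maps a domain name (e.g. ``"episodic memory"``) to the list
    of test-score column names that enter its composite.  A test belongs to
    exactly one scoring domain; ``display`` may carry extra annotation
    labels (e.g. a semantic-fluency test shown as "sem/lan") that do not
    affect scoring.  All tests are oriented so that a higher score means
    better performance.
    """

    domains: dict[str, list[str]]
    display: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for dom, tests in self.domains.items():
            for t in tests:
                if t in seen:
                    raise ValidationError(
                        f"test {t!r} mapped to both {seen[t]!r} and {dom!r}"
                    )
                seen[t] = dom

    @property
    def tests(self) -> list[str]:
        out: list[str] = []
        for tests in self.domains.values():
            out.extend(tests)
        return out

    def domain_of(self, test: str) -> str:
        for dom, tests in self.domains.items():
            if test in tests:
                return dom
        raise KeyError(test)


# The 19-test battery referable to five cognitive domains, with the short
# hub labels used in network exports.
DOMAIN_HUB_LABELS = {
    "episodic memory": "epis.mem",
    "semantic memory": "sem.mem",
    "working memory": "work.mem",
    "perceptual orientation": "perc.or",
    "perceptual speed": "perc.sp",
}


def default_domain_map() -> DomainMap:
    """The default 19-test battery grouped into five cognitive domains."""
    return DomainMap(
        domains={
            "episodic memory": [
                "log.mem.imm",
                "log.mem.del",
                "east.bost.imm",
                "east.bost.del.recall",
                "word.list.recall",
                "word.list.recogn",
            ],
            "semantic memory": [
                "bost.nam",
                "cat.fluenc",
                "ext.rang.voc",
                "read.test",
            ],
            "working memory": [
                "alph.span",
                "dig.order",
                "dig.forw",
                "dig.backw",
            ],
            "perceptual orientation": [
                "progr.matr",
                "progr.matr.subs",
                "line.orient",
            ],
            "perceptual speed": ["numb.comp", "symb.dig.oral"],
        },
        display={"cat.fluenc": "sem/lan", "symb.dig.oral": "spe/att"},
    )


_COHORT_REQUIRED = [
    "subject_id",
    "age_at_death",
    "sex",
    "education",
    "apoe",
    "mmse",
    "gcs",
    "braak",
    "cerad",
    "nia_reagan",
    "amyloid_load_6e10",
    "tangle_load_at8",
]


class CohortTable:
    """Validated per-subject phenotype table.

    Wraps a DataFrame with one row per subject carrying demographics
    (age at death, sex, education, ApoE), global cognition (MMSE 0-30 and
    the global composite z-score GCS), the individual test battery, and
    ordinal neuropathology (Braak stage, CERAD, NIA-Reagan, semi-
    quantitative 6E10 amyloid and AT8 tangle loads, 0-5).  A ``group``
    column ('I-II', 'III', 'IV') is derived from Braak stage.
    """

    def __init__(self, df: pd.DataFrame, tests: list[str] | None = None):
        df = df.copy()
        missing = [c for c in _COHORT_REQUIRED if c not in df.columns]
        if missing:
            raise ValidationError(f"missing required columns: {missing}")
        if df["subject_id"].duplicated().any():
            dupes = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
            raise ValidationError(f"duplicate subject ids: {dupes}")
        for col, levels in [
            ("sex", SEX_LEVELS),
            ("apoe", APOE_LEVELS),
            ("braak", BRAAK_LEVELS),
            ("cerad", CERAD_LEVELS),
            ("nia_reagan", NIA_REAGAN_LEVELS),
        ]:
            bad = set(df[col].dropna()) - set(levels)
            if bad:
                raise ValidationError(f"unknown {col} level(s): {sorted(bad)}")
        mmse = df["mmse"].dropna()
        if ((mmse < 0) | (mmse > 30)).any():
            bad_ids = df.loc[(df["mmse"] < 0) | (df["mmse"] > 30), "subject_id"]
            raise ValidationError(f"mmse outside [0, 30] for {bad_ids.tolist()}")
        for col in ("amyloid_load_6e10", "tangle_load_at8"):
            v = df[col].dropna()
            if ((v < 0) | (v > 5)).any():
                raise ValidationError(f"{col} outside [0, 5]")
        df["group"] = df["braak"].map(braak_group)
        if tests is None:
            tests = [c for c in df.columns if c not in _COHORT_REQUIRED + ["group"]]
        else:
            missing_t = [t for t in tests if t not in df.columns]
            if missing_t:
                raise ValidationError(f"missing test columns: {missing_t}")
        self.df = df.reset_index(drop=True)
        self.tests = list(tests)

    @property
    def n_subjects(self) -> int:
        return len(self.df)

    @property
    def subject_ids(self) -> list[str]:
        return self.df["subject_id"].tolist()

    def ordinal(self, column: str) -> pd.Series:
        """Numeric encoding of an ordinal column, aligned to subjects."""
        return self.df[column].map(lambda v: ordinal_code(column, v))

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"CohortTable(n={self.n_subjects}, tests={len(self.tests)})"


class ExpressionMatrix:
    """miRNA x subject count matrix with explicit presence semantics.

    ``counts`` holds non-negative values, rows indexed by miRNA id and
    columns by subject id.  A miRNA is *present* in a subject when its
    count is strictly positive; absence is encoded as a zero count, never
    as a missing value.  ``normalized`` marks matrices whose subject
    columns have been divided by the subject's total (columns then sum to
    1 within 1e-9).
    """

    def __init__(self, counts: pd.DataFrame, normalized: bool = False):
        if counts.index.duplicated().any():
            dupes = counts.index[counts.index.duplicated()].tolist()
            raise ValidationError(f"duplicate miRNA ids: {dupes}")
        arr = counts.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            raise ValidationError("counts contain non-finite values")
        if (arr < 0).any():
            i, j = np.argwhere(arr < 0)[0]
            raise ValidationError(
                f"negative count at miRNA {counts.index[i]!r}, "
                f"subject {counts.columns[j]!r}"
            )
        if normalized:
            # a freshly normalized matrix sums to 1 per column; a presence-
            # filtered subset of one may sum to less, never more
            sums = arr.sum(axis=0)
            if (sums > 1.0 + 1e-9).any():
                raise ValidationError("normalized matrix column sums exceed 1")
        self.counts = counts
        self.normalized = normalized

    @property
    def mirna_ids(self) -> list[str]:
        return self.counts.index.tolist()

    @property
    def subject_ids(self) -> list[str]:
        return self.counts.columns.tolist()

    @property
    def presence(self) -> pd.DataFrame:
        return self.counts > 0

    @property
    def n_present(self) -> pd.Series:
        """Number of subjects in which each miRNA is present (count > 0)."""
        return self.presence.sum(axis=1)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        kind = "normalized" if self.normalized else "raw"
        return f"ExpressionMatrix({self.shape[0]} miRNAs x {self.shape[1]} subjects, {kind})"


@dataclass(frozen=True)
class AssociationRecord:
    """One miRNA-phenotype association from the screen."""

    mirna_id: str
    phenotype_id: str
    statistic_kind: str  # 'spearman_rho' | 'point_biserial_r'
    rho: float
    p_value: float
    n_used: int
    q_value: float | None = None

    def __post_init__(self) -> None:
        if not -1.0 <= self.rho <= 1.0:
            raise ValidationError(f"rho outside [-1, 1]: {self.rho}")
        if not 0.0 < self.p_value <= 1.0:
            raise ValidationError(f"p outside (0, 1]: {self.p_value}")

    @property
    def sign(self) -> str:
        return "positive" if self.rho > 0 else "negative"


RECORD_COLUMNS = [
    "mirna",
    "phenotype",
    "statistic_kind",
    "rho",
    "p",
    "q",
    "n_used",
    "sign",
    "highlight",
]


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable screen parameters.

    alpha
        Uncorrected two-sided significance cut-off for keeping an
        association (default 0.05).
    fdr_q
        When set (the conventional boundary is 0.1), Benjamini-Hochberg
        q-values are computed across the full pre-filter record set and
        records must additionally satisfy q <= fdr_q.  Off by default: the
        primary screen is deliberately uncorrected.
    min_present
        A miRNA must have a nonzero count in at least this many subjects
        to enter the screen (default 11).
    highlight_alpha
        Records with p below this level are flagged for emphasis
        (default 0.0005).
    logit_min / tarbase_min_score
        Thresholds for the target-prediction connectivity analysis.
    """

    alpha: float = 0.05
    fdr_q: float | None = None
    min_present: int = 11
    highlight_alpha: float = 0.0005
    seed: int = 0
    logit_min: float = 0.5
    tarbase_min_score: float = 0.8
    pairwise_complete: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValidationError(f"alpha outside (0, 1): {self.alpha}")
        if self.min_present < 1:
            raise ValidationError("min_present must be >= 1")
        if self.fdr_q is not None and not 0.0 < self.fdr_q < 1.0:
            raise ValidationError(f"fdr_q outside (0, 1): {self.fdr_q}")

    def replace(self, **kw) -> "AnalysisConfig":
        return replace(self, **kw)


_INTERACTION_COLUMNS = [
    "mirna",
    "gene",
    "accession",
    "site",
    "logit_prob",
    "category",
    "source",
    "source_score",
]


class InteractionTable:
    """Predicted miRNA-mRNA interaction sites.

    Each row is one predicted binding site: miRNA id, target gene symbol
    and accession, a site descriptor, the predictor's logit probability
    that the site is functional, the gene's pathway category, and the
    record source ('starmir-like' sequence predictions carry only the
    logit probability; 'tarbase-like' curated records additionally carry
    a validation ``source_score``).
    """

    def __init__(self, df: pd.DataFrame, panel: pd.DataFrame | None = None):
        df = df.copy()
        missing = [c for c in _INTERACTION_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"missing interaction columns: {missing}")
        bad_cat = set(df["category"].dropna()) - set(INTERACTION_CATEGORIES)
        if bad_cat:
            raise ValidationError(f"unknown category: {sorted(bad_cat)}")
        bad_src = set(df["source"].dropna()) - set(INTERACTION_SOURCES)
        if bad_src:
            raise ValidationError(f"unknown source: {sorted(bad_src)}")
        lp = pd.to_numeric(df["logit_prob"], errors="coerce")
        if len(df) and lp.isna().any():
            raise ValidationError("logit_prob must be finite numeric")
        df["logit_prob"] = lp
        df["source_score"] = pd.to_numeric(df["source_score"], errors="coerce")
        if panel is not None and len(df):
            known = set(panel["gene"])
            bad = set(df["gene"]) - known
            if bad:
                raise ValidationError(f"genes not in panel: {sorted(bad)}")
        self.df = df[_INTERACTION_COLUMNS].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"InteractionTable({len(self)} sites)"
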