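"""Synthetic cohort and count-matrix generator.

The generator emulates the statistical structure the screen assumes: a
26-subject autopsy cohort split 8/8/10 across Braak-stage groups
I-II/III/IV with the published per-group categorical composition (sex,
ApoE, CERAD, NIA-Reagan), group-dependent ages and pathology loads, a
19-test cognitive battery built from five latent domain abilities, and a
~900-miRNA negative-binomial count matrix whose per-miRNA presence rates
span 42-100% of subjects.  Selected miRNAs are coupled to chosen
phenotypes through a Gaussian copula calibrated so the *population*
Spearman correlation equals the planted target (Pearson latent
correlation r = 2 sin(pi * rho / 6)); all other miRNAs are independent
of every phenotype.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import (
    CohortTable,
    ExpressionMatrix,
    ValidationError,
    default_domain_map,
)
from .fixtures import GROUP_LABELS, cohort_contingency_tables

__all__ = ["SimulationSpec", "default_planted_effects", "simulate_cohort", "simulate_counts", "ground_truth"]


def default_planted_effects() -> list[tuple[str, str, float]]:
    """Default planted associations, echoing the observed pattern:

    positive couplings with age and the perceptual domains, negative with
    semantic/episodic memory, mixed with Braak stage; strengths 0.4-0.8.
    """
    return [
        ("miR-s0001", "age", 0.6),
        ("miR-s0002", "age", 0.5),
        ("miR-s0003", "perc.or", 0.55),
        ("miR-s0004", "perc.sp", 0.5),
        ("miR-s0005", "sem.mem", -0.6),
        ("miR-s0006", "sem.mem", -0.5),
        ("miR-s0007", "epis.mem", -0.5),
        ("miR-s0008", "braak", 0.6),
        ("miR-s0009", "braak", -0.5),
        ("miR-s0010", "mmse", 0.45),
        ("miR-s0011", "educ", 0.5),
        ("miR-s0012", "glob.cog", -0.45),
    ]


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of the synthetic study.

    nb_mean_log_range is the log10 range of per-miRNA negative-binomial
    means; nb_dispersion is alpha in Var = mu + alpha*mu^2 (0 = Poisson
    limit); library_size_cv spreads per-subject sequencing depth;
    test_noise_sd is the residual SD added to each test around its
    domain latent (latents are standard normal).
    """

    n_subjects: int = 26
    group_sizes: tuple[int, int, int] = (8, 8, 10)
    n_mirna: int = 906
    presence_rate_range: tuple[float, float] = (0.42, 1.0)
    planted_effects: list[tuple[str, str, float]] = field(
        default_factory=default_planted_effects
    )
    nb_mean_log_range: tuple[float, float] = (0.5, 3.0)
    nb_dispersion: float = 0.3
    library_size_cv: float = 0.3
    test_noise_sd: float = 0.6
    n_missing_loads: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.group_sizes) != self.n_subjects:
            raise ValidationError(
                f"group_sizes {self.group_sizes} do not sum to n_subjects {self.n_subjects}"
            )
        lo, hi = self.presence_rate_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ValidationError(f"presence_rate_range outside (0, 1]: {self.presence_rate_range}")
        for mid, phen, rho in self.planted_effects:
            if not abs(rho) < 1.0:
                raise ValidationError(f"|target_rho| must be < 1 for {mid}/{phen}: {rho}")
        if self.nb_dispersion < 0 or self.library_size_cv < 0 or self.test_noise_sd < 0:
            raise ValidationError("dispersion, library CV and noise SD must be >= 0")

    def mirna_ids(self) -> list[str]:
        return [f"miR-s{i:04d}" for i in range(1, self.n_mirna + 1)]


# Group-dependent continuous ranges (min, max) mirroring the published
# per-group summaries; uniform draws within them preserve the published
# age-Braak association.
_AGE_RANGE = {"I-II": (76.0, 92.0), "III": (82.0, 96.0), "IV": (83.0, 93.0)}
_EDUC_RANGE = {"I-II": (12.0, 21.0), "III": (14.0, 21.0), "IV": (14.0, 27.0)}
_MMSE_RANGE = {"I-II": (25, 30), "III": (26, 30), "IV": (26, 30)}
_LOAD_6E10_MEAN = {"I-II": 2.6, "III": 2.8, "IV": 4.6}
_LOAD_AT8_MEAN = {"I-II": 0.6, "III": 0.7, "IV": 2.2}


def _alloc_levels(levels, counts, size: int, rng) -> np.ndarray:
    """Assign categorical levels to ``size`` subjects.

    When ``size`` matches the reference total the exact reference counts
    are used (shuffled); otherwise levels are drawn from the reference
    proportions.
    """
    counts = np.asarray(counts)
    if counts.sum() == size:
        out = np.repeat(levels, counts)
    else:
        out = rng.choice(levels, size=size, p=counts / counts.sum())
    return rng.permutation(out)


def simulate_cohort(spec: SimulationSpec) -> CohortTable:
    """Draw a cohort with the configured group structure.

    Categorical composition per group follows the packaged published
    contingency tables exactly when group sizes match (8/8/10);
    cognitive tests are domain latents plus noise and GCS is the mean of
    the 19 per-test z-scores.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0]))
    dm = default_domain_map()
    tabs = cohort_contingency_tables()
    rows = []
    sid = 0
    for group, size in zip(GROUP_LABELS, spec.group_sizes):
        if group == "I-II":
            braak = rng.permutation(["I"] * (size // 2) + ["II"] * (size - size // 2))
        else:
            braak = np.array([group] * size)
        sex = _alloc_levels(tabs["sex"].columns.to_numpy(), tabs["sex"].loc[group], size, rng)
        apoe = _alloc_levels(tabs["apoe"].columns.to_numpy(), tabs["apoe"].loc[group], size, rng)
        cerad = _alloc_levels(tabs["cerad"].columns.to_numpy(), tabs["cerad"].loc[group], size, rng)
        nia = _alloc_levels(
            tabs["nia_reagan"].columns.to_numpy(), tabs["nia_reagan"].loc[group], size, rng
        )
        age = rng.uniform(*_AGE_RANGE[group], size=size)
        educ = rng.uniform(*_EDUC_RANGE[group], size=size)
        mmse = rng.integers(_MMSE_RANGE[group][0], _MMSE_RANGE[group][1] + 1, size=size)
        amy = np.clip(np.round(rng.normal(_LOAD_6E10_MEAN[group], 0.8, size=size)), 0, 5)
        tau = np.clip(np.round(rng.normal(_LOAD_AT8_MEAN[group], 0.8, size=size)), 0, 5)
        for k in range(size):
            rows.append(
                {
                    "subject_id": f"S{sid + 1:02d}",
                    "age_at_death": age[k],
                    "sex": sex[k],
                    "education": educ[k],
                    "apoe": apoe[k],
                    "mmse": int(mmse[k]),
                    "braak": braak[k],
                    "cerad": cerad[k],
                    "nia_reagan": nia[k],
                    "amyloid_load_6e10": float(amy[k]),
                    "tangle_load_at8": float(tau[k]),
                }
            )
            sid += 1
    df = pd.DataFrame(rows)

    n = len(df)
    latents = rng.standard_normal((n, len(dm.domains)))
    for d, (domain, tests) in enumerate(dm.domains.items()):
        for t in tests:
            df[t] = latents[:, d] + spec.test_noise_sd * rng.standard_normal(n)
    z = df[dm.tests] - df[dm.tests].mean()
    sd = df[dm.tests].std(ddof=1)
    sd = sd.replace(0.0, 1.0)  # noise-free battery: constant offsets only
    df["gcs"] = (z / sd).mean(axis=1)

    if spec.n_missing_loads > 0:
        stage3 = df.index[df["braak"] == "III"].to_numpy()
        k = min(spec.n_missing_loads, len(stage3))
        if k:
            drop = rng.choice(stage3, size=k, replace=False)
            df.loc[drop, ["amyloid_load_6e10", "tangle_load_at8"]] = np.nan
    return CohortTable(df, tests=dm.tests)


def _nb_ppf(u: np.ndarray, mu: np.ndarray, alpha: float) -> np.ndarray:
    """Quantile transform to a negative binomial with Var = mu + alpha mu^2."""
    if alpha == 0:
        return stats.poisson.ppf(u, mu)
    size = 1.0 / alpha
    p = size / (size + mu)
    return stats.nbinom.ppf(u, size, p)


def simulate_counts(spec: SimulationSpec, cohort: CohortTable) -> ExpressionMatrix:
    """Draw the miRNA x subject count matrix.

    Marginals are negative binomial with per-miRNA means spread over
    ``nb_mean_log_range`` (log10) and per-subject lognormal library-size
    factors.  Planted miRNAs couple to their phenotype via the Gaussian
    copula (r = 2 sin(pi rho / 6)); per-miRNA zero-inflation implements
    the presence-rate range, with planted miRNAs exempt (presence 1) so
    the planted correlation is the population value.
    """
    from .association import phenotype_frame

    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    ids = spec.mirna_ids()
    n_m, n_s = spec.n_mirna, cohort.n_subjects
    planted = {mid: (phen, rho) for mid, phen, rho in spec.planted_effects}
    unknown = set(planted) - set(ids)
    if unknown:
        raise ValidationError(f"planted miRNA ids outside the simulated set: {sorted(unknown)}")

    pheno = phenotype_frame(cohort, default_domain_map())
    for mid, (phen, _) in planted.items():
        if phen not in pheno.columns:
            raise ValidationError(f"planted phenotype {phen!r} not in cohort")

    log_mu = rng.uniform(*spec.nb_mean_log_range, size=n_m)
    mu = 10.0**log_mu
    if spec.library_size_cv > 0:
        sig2 = np.log1p(spec.library_size_cv**2)
        lib = rng.lognormal(-sig2 / 2.0, np.sqrt(sig2), size=n_s)
    else:
        lib = np.ones(n_s)
    mu_mat = mu[:, None] * lib[None, :]

    z = rng.standard_normal((n_m, n_s))
    for i, mid in enumerate(ids):
        if mid not in planted:
            continue
        phen, rho = planted[mid]
        y = pheno[phen].to_numpy(dtype=float)
        ok = np.isfinite(y)
        zp = np.zeros(n_s)
        ranks = stats.rankdata(y[ok], method="average")
        zp[ok] = stats.norm.ppf((ranks - 0.5) / ok.sum())
        r = 2.0 * np.sin(np.pi * rho / 6.0)
        z[i] = r * zp + np.sqrt(1.0 - r * r) * z[i]

    u = stats.norm.cdf(z)
    counts = _nb_ppf(u, mu_mat, spec.nb_dispersion)

    presence = rng.uniform(*spec.presence_rate_range, size=n_m)
    for i, mid in enumerate(ids):
        if mid in planted:
            presence[i] = 1.0
    # the NB marginal already has zero mass; shrink the inflation
    # probability so the *population* presence rate hits the target
    if spec.nb_dispersion == 0:
        p_zero = np.exp(-mu_mat).mean(axis=1)
    else:
        size = 1.0 / spec.nb_dispersion
        p_zero = ((size / (size + mu_mat)) ** size).mean(axis=1)
    keep = np.clip(presence / np.maximum(1.0 - p_zero, 1e-12), 0.0, 1.0)
    drop = rng.random((n_m, n_s)) > keep[:, None]
    counts = np.where(drop, 0.0, counts)

    df = pd.DataFrame(counts, index=pd.Index(ids, name="mirna"), columns=cohort.subject_ids)
    return ExpressionMatrix(df, normalized=False)


def ground_truth(spec: SimulationSpec) -> pd.DataFrame:
    """Exact echo of the planted effects, for recovery tests."""
    return pd.DataFrame(spec.planted_effects, columns=["mirna", "phenotype", "target_rho"])
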