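"""Synthetic post-mortem cohort tables with planted rank correlations.

Emulates the statistical structure of a 47-case MS / 10-control cohort:
per-stratum (genotype) group means for microglial markers, lymphocytes
and neuron density, plus genotype-dependent Spearman correlations between
marker expression and neuron density, planted through a Gaussian copula.

The copula plants a target Spearman r_s by giving the latent Gaussian
pair the Pearson correlation ρ = 2·sin(π·r_s/6) (the exact bivariate-
normal relationship between the two coefficients); monotone marginal
transforms then preserve the rank correlation, so marker marginals can
be right-skewed log-normals while neuron density stays near-normal.
Markers are conditionally independent given neuron density unless an
explicit marker–marker correlation is configured.
"""

from __future__ import annotations

import io as _io
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ConfigurationError, EmptyInputError
from .types import CaseRecord

#: variables drawn through the copula, in column order
COPULA_MARKERS = ("iba1", "cd68", "tmem119", "gfap", "cd3", "cd8", "fibrinogen")

#: strata and their genotype labels
STRATA = ("DRB15_pos", "DRB15_neg", "control")


@dataclass
class MarginalSpec:
    mean: float
    sd: float
    dist: str = "lognormal"  # "lognormal" | "normal" (truncated at 0)


def _default_marginals() -> dict[str, dict[str, MarginalSpec]]:
    """Per-stratum marginal means/SDs.

    Means are the printed group means; SDs are back-computed from the
    printed SEMs as SEM·√n (MS n = 47, control n = 10). MS strata share
    the whole-group marginals: the genotype groups differed in their
    correlation structure, not materially in their means.
    """
    ms = {
        "iba1": MarginalSpec(6.18, 0.55 * math.sqrt(47)),
        "cd68": MarginalSpec(1.77, 0.32 * math.sqrt(47)),
        "tmem119": MarginalSpec(0.47, 0.23 * math.sqrt(47)),
        "gfap": MarginalSpec(0.85, 0.39 * math.sqrt(47)),
        "cd3": MarginalSpec(4.16, 0.62 * math.sqrt(47)),
        "cd8": MarginalSpec(1.77, 0.31 * math.sqrt(47)),
        "fibrinogen": MarginalSpec(1.0, 0.8),
        "neuron_density": MarginalSpec(414, 17 * math.sqrt(47), dist="normal"),
    }
    control = {
        "iba1": MarginalSpec(6.16, 0.7 * math.sqrt(10)),
        "cd68": MarginalSpec(1.35, 0.32 * math.sqrt(10)),
        "tmem119": MarginalSpec(0.49, 0.23 * math.sqrt(10)),
        "gfap": MarginalSpec(0.84, 0.43 * math.sqrt(10)),
        "cd3": MarginalSpec(0.88, 0.25 * math.sqrt(10)),
        "cd8": MarginalSpec(0.10, 0.07 * math.sqrt(10)),
        "fibrinogen": MarginalSpec(0.4, 0.35),
        "neuron_density": MarginalSpec(431, 27 * math.sqrt(10), dist="normal"),
    }
    return {"DRB15_pos": dict(ms), "DRB15_neg": dict(ms), "control": control}


def _default_spearman_targets() -> dict[str, dict[str, float]]:
    """Planted Spearman correlations of each marker with neuron density.

    The carrier stratum shows no microglia–neuron relationship while the
    non-carrier stratum shows strong positive ones; fibrinogen burden is
    planted mildly negative against neuron density in MS (no canonical
    magnitude exists for it, so it is configurable).
    """
    return {
        "DRB15_neg": {"iba1": 0.740, "cd68": 0.632, "tmem119": 0.522,
                      "gfap": 0.196, "cd3": -0.074, "cd8": 0.193,
                      "fibrinogen": -0.30},
        "DRB15_pos": {"iba1": 0.207, "cd68": 0.185, "tmem119": 0.355,
                      "gfap": 0.196, "cd3": -0.074, "cd8": 0.193,
                      "fibrinogen": -0.30},
        "control": {"iba1": 0.07, "cd68": 0.33, "tmem119": 0.26,
                    "gfap": -0.143, "cd3": -0.216, "cd8": -0.134,
                    "fibrinogen": 0.0},
    }


@dataclass
class CohortConfig:
    """Layout and planted structure of the synthetic cohort."""

    n_ms_pos: int = 21
    n_ms_neg: int = 26
    n_control: int = 10
    seed: int = 0
    target_spearman: dict = field(default_factory=_default_spearman_targets)
    marginals: dict = field(default_factory=_default_marginals)
    #: optional explicit latent marker–marker Pearson overrides,
    #: {(var_a, var_b): rho}; default is conditional independence given
    #: neuron density
    latent_overrides: dict = field(default_factory=dict)
    #: P(male) per stratum
    sex_p_male: dict = field(default_factory=lambda: {
        "DRB15_pos": 7 / 21, "DRB15_neg": 6 / 26, "control": 7 / 10})
    age_mean_sd: dict = field(default_factory=lambda: {
        "DRB15_pos": (65, 13), "DRB15_neg": (62, 11), "control": (74, 9)})
    age_range: tuple = (35, 95)
    pmi_mean_sd: dict = field(default_factory=lambda: {
        "DRB15_pos": (18, 8), "DRB15_neg": (18, 5), "control": (36.7, 16)})
    duration_mean_sd: tuple = (31, 12)
    #: per-case means of the synapse sub-study variables
    coverage_mean_sd: dict = field(default_factory=lambda: {
        "DRB15_pos": (0.300, 0.025), "DRB15_neg": (0.297, 0.025),
        "control": (0.348, 0.025)})
    size_mean_sd: dict = field(default_factory=lambda: {
        "DRB15_pos": (376, 55), "DRB15_neg": (432, 55), "control": (531, 60)})

    def validate(self) -> None:
        for name, n in (("n_ms_pos", self.n_ms_pos),
                        ("n_ms_neg", self.n_ms_neg),
                        ("n_control", self.n_control)):
            if n <= 0:
                raise ConfigurationError("stratum counts must be > 0", [name])
        bad = [f"{s}.{v}" for s, d in self.target_spearman.items()
               for v, r in d.items() if not abs(r) < 1]
        if bad:
            raise ConfigurationError("|target Spearman| must be < 1", bad)


def spearman_to_pearson_latent(r_s: float) -> float:
    """Latent bivariate-normal Pearson ρ giving Spearman r_s: 2·sin(π·r_s/6)."""
    return 2.0 * math.sin(math.pi * r_s / 6.0)


def _latent_correlation(targets: dict[str, float],
                        overrides: dict) -> tuple[list[str], np.ndarray]:
    """Full latent correlation matrix over (markers..., neuron_density).

    Marker–marker entries default to ρ_i·ρ_j (conditional independence
    given the neuron-density factor), which is positive definite by
    construction; explicit overrides trigger a feasibility check.
    """
    variables = [v for v in COPULA_MARKERS if v in targets] + ["neuron_density"]
    k = len(variables)
    rho = np.array([spearman_to_pearson_latent(targets[v]) for v in variables[:-1]])
    R = np.empty((k, k))
    R[:-1, :-1] = np.outer(rho, rho)
    R[:-1, -1] = R[-1, :-1] = rho
    np.fill_diagonal(R, 1.0)
    for (a, b), r in overrides.items():
        ia, ib = variables.index(a), variables.index(b)
        R[ia, ib] = R[ib, ia] = float(r)
    try:
        np.linalg.cholesky(R + 1e-12 * np.eye(k))
    except np.linalg.LinAlgError:
        raise ConfigurationError(
            "latent correlation matrix is not positive definite",
            [f"{a}~{b}" for (a, b) in overrides],
        ) from None
    return variables, R


def _marginal_ppf(u: np.ndarray, spec: MarginalSpec) -> np.ndarray:
    if spec.dist == "lognormal":
        sigma2 = math.log(1.0 + (spec.sd / spec.mean) ** 2)
        mu = math.log(spec.mean) - sigma2 / 2.0
        return np.exp(sps.norm.ppf(u, loc=mu, scale=math.sqrt(sigma2)))
    if spec.dist == "normal":
        a = -spec.mean / spec.sd  # truncate at zero: densities are non-negative
        return sps.truncnorm.ppf(u, a=a, b=np.inf, loc=spec.mean, scale=spec.sd)
    raise ConfigurationError(f"unknown marginal distribution {spec.dist!r}")


def simulate_stratum(
    n: int,
    targets: dict[str, float],
    marginals: dict[str, MarginalSpec],
    rng: np.random.Generator,
    latent_overrides: Optional[dict] = None,
) -> pd.DataFrame:
    """Draw one stratum's (markers, neuron_density) block from the copula."""
    variables, R = _latent_correlation(targets, latent_overrides or {})
    L = np.linalg.cholesky(R + 1e-12 * np.eye(len(variables)))
    z = rng.standard_normal((n, len(variables))) @ L.T
    u = sps.norm.cdf(z)
    return pd.DataFrame(
        {v: _marginal_ppf(u[:, i], marginals[v]) for i, v in enumerate(variables)}
    )


def simulate_cohort(config: Optional[CohortConfig] = None) -> list[CaseRecord]:
    """Generate the full per-case cohort table.

    Reproducible under ``config.seed``; covariates are drawn
    independently of the copula block.
    """
    config = config or CohortConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    records: list[CaseRecord] = []
    layout = [("DRB15_pos", config.n_ms_pos, "MS"),
              ("DRB15_neg", config.n_ms_neg, "MS"),
              ("control", config.n_control, "control")]
    for stratum, n, group in layout:
        block = simulate_stratum(n, config.target_spearman[stratum],
                                 config.marginals[stratum], rng,
                                 config.latent_overrides)
        a_mean, a_sd = config.age_mean_sd[stratum]
        lo, hi = config.age_range
        ages = sps.truncnorm.ppf(rng.random(n), a=(lo - a_mean) / a_sd,
                                 b=(hi - a_mean) / a_sd, loc=a_mean, scale=a_sd)
        p_mean, p_sd = config.pmi_mean_sd[stratum]
        pmis = sps.truncnorm.ppf(rng.random(n), a=-p_mean / p_sd + 0.3,
                                 b=np.inf, loc=p_mean, scale=p_sd)
        sexes = np.where(rng.random(n) < config.sex_p_male[stratum], "M", "F")
        d_mean, d_sd = config.duration_mean_sd
        durations = np.clip(rng.normal(d_mean, d_sd, n), 5, None)
        c_mean, c_sd = config.coverage_mean_sd[stratum]
        covs = np.clip(rng.normal(c_mean, c_sd, n), 0, None)
        s_mean, s_sd = config.size_mean_sd[stratum]
        sizes = np.clip(rng.normal(s_mean, s_sd, n), 50, None)
        for i in range(n):
            records.append(CaseRecord(
                case_id=f"{stratum}_{i:03d}",
                group=group,
                genotype=stratum if group == "MS" else "not_applicable",
                age_death=float(ages[i]),
                sex=str(sexes[i]),
                pm_interval=float(pmis[i]),
                disease_duration=float(durations[i]) if group == "MS" else None,
                fibrinogen=float(block["fibrinogen"].iloc[i]),
                iba1=float(block["iba1"].iloc[i]),
                cd68=float(block["cd68"].iloc[i]),
                tmem119=float(block["tmem119"].iloc[i]),
                gfap=float(block["gfap"].iloc[i]),
                cd3=float(block["cd3"].iloc[i]),
                cd8=float(block["cd8"].iloc[i]),
                neuron_density=float(block["neuron_density"].iloc[i]),
                mean_coverage=float(covs[i]),
                mean_neuron_size=float(sizes[i]),
            ))
    return records


_COLUMNS = [
    "case_id", "group", "genotype", "age_death", "sex", "pm_interval",
    "disease_duration", "fibrinogen", "iba1", "cd68", "tmem119", "gfap",
    "cd3", "cd8", "neuron_density", "mean_coverage", "mean_neuron_size",
]

_COLUMN_DICT = {
    "case_id": "case identifier",
    "group": "MS | control",
    "genotype": "DRB15_pos | DRB15_neg | not_applicable (controls)",
    "age_death": "age at death, years",
    "sex": "M | F",
    "pm_interval": "post-mortem interval, hours",
    "disease_duration": "years; empty for controls",
    "fibrinogen": "fibrinogen burden, arbitrary units",
    "iba1": "Iba1+ expression, millions of pixels/mm2",
    "cd68": "CD68+ expression, millions of pixels/mm2",
    "tmem119": "TMEM119+ expression, millions of pixels/mm2",
    "gfap": "GFAP+ coverage, millions of pixels/mm2",
    "cd3": "CD3+ lymphocytes, cells/mm2",
    "cd8": "CD8+ lymphocytes, cells/mm2",
    "neuron_density": "NeuN+ neurons/mm2",
    "mean_coverage": "case-mean inhibitory synaptic coverage, puncta/um2",
    "mean_neuron_size": "case-mean neuron size, um2",
}


def records_to_frame(records: list[CaseRecord]) -> pd.DataFrame:
    if not records:
        raise EmptyInputError("no cohort records")
    return pd.DataFrame([vars(r) for r in records], columns=_COLUMNS)


def emit_cohort_csv(records: list[CaseRecord], path: str) -> None:
    """Write the cohort as CSV with a column dictionary in header comments.

    Missing values (e.g. controls' disease duration) are written as empty
    fields, not zero.
    """
    frame = records_to_frame(records)
    buf = _io.StringIO()
    for col in _COLUMNS:
        buf.write(f"# {col}: {_COLUMN_DICT[col]}\n")
    frame.to_csv(buf, index=False)
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def read_cohort_csv(path: str) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
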