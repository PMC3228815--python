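"""Synthetic data generation for power and type-I error studies.

Emulates the structure of a population resequencing study of one candidate
gene: a mixed spectrum of common (MAF >= 1%) and rare (down to singleton)
variants in Hardy-Weinberg proportions, a three-level ancestry factor plus
age, sex and BMI as covariates, two common "singleton" variants handled as
covariates, and a continuous log-scale trait with residual SD 0.2 (a binary
trait is derived by a median split of the continuous one).

Per-group variant effects are drawn uniformly from [0, beta_h] with an
independent sign flip with probability ``p_neg``; the upper bound beta_h is
calibrated so a group of variants explains a target fraction ``h`` of the
phenotypic variance:

    Var(sum_j beta_j z_j) ~= (beta_h^2 / 3) * sum_j 2 q_j (1 - q_j)
    h = V_g / (V_g + sigma_e^2)  =>  beta_h = sqrt(3 h sigma_e^2
                                       / ((1 - h) sum_j 2 q_j (1 - q_j))).

Genotypes are simulated independently (no linkage disequilibrium).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import GenotypeMatrix

__all__ = [
    "Scenario",
    "SimulatedDataset",
    "simulate_genotypes",
    "maf_spectrum",
    "compute_beta_h",
    "simulate_effects",
    "simulate_phenotype",
    "simulate_dataset",
    "scenario_catalog",
    "SCENARIO_GROUP_SIZES",
]

#: group sizes printed in the study-design tables, keyed by (layout, n)
SCENARIO_GROUP_SIZES = {
    ("three_groups", 3008): (10, 26, 44),
    ("three_groups", 1499): (11, 16, 34),
    ("six_groups", 3008): (5, 5, 13, 13, 22, 22),
    ("six_groups", 1499): (5, 6, 8, 8, 17, 17),
}

#: which groups hold common variants (the rest are rare)
_COMMON_GROUPS = {"three_groups": (0,), "six_groups": (0, 1)}

_SCENARIOS_THREE = {
    # scenario -> per-group (h, p_neg)
    "a": ((0.0, 0.0), (0.005, 0.0), (0.0, 0.0)),
    "b": ((0.0, 0.0), (0.007, 0.4), (0.0, 0.0)),
    "c": ((0.005, 0.0), (0.005, 0.0), (0.0, 0.0)),
    "d": ((0.007, 0.4), (0.007, 0.4), (0.0, 0.0)),
    "e": ((0.0, 0.0), (0.007, 0.0), (0.007, 0.0)),
    "f": ((0.0, 0.0), (0.007, 0.4), (0.007, 0.4)),
}
_SCENARIOS_SIX = {
    "a": ((0.0, 0.0), (0.005, 0.0), (0.0, 0.0),
          (0.0, 0.0), (0.005, 0.0), (0.0, 0.0)),
    "b": ((0.0, 0.0), (0.007, 0.4), (0.0, 0.0),
          (0.0, 0.0), (0.007, 0.4), (0.0, 0.0)),
    "c": ((0.0, 0.0), (0.0, 0.0), (0.005, 0.0),
          (0.0, 0.0), (0.005, 0.0), (0.0, 0.0)),
    "d": ((0.0, 0.0), (0.0, 0.0), (0.007, 0.4),
          (0.0, 0.0), (0.007, 0.4), (0.0, 0.0)),
}


@dataclass(frozen=True)
class Scenario:
    """One simulation configuration."""

    n: int
    group_sizes: tuple[int, ...]
    h: tuple[float, ...]                    # per-group heritability targets
    p_neg: tuple[float, ...]                # per-group sign-flip probabilities
    trait: str = "continuous"               # 'continuous' or 'binary'
    sigma_e: float = 0.2
    common_groups: tuple[int, ...] = (0,)   # indices of common-MAF groups
    covariate_effects: dict = field(default_factory=dict)
    singleton_mafs: tuple[float, ...] = (0.030, 0.016)
    singleton_effects: tuple[float, ...] = (0.0, 0.0)
    name: str = ""

    def __post_init__(self):
        if not (len(self.group_sizes) == len(self.h) == len(self.p_neg)):
            raise ValueError("group_sizes, h and p_neg must align")
        if any(j < 2 for j in self.group_sizes):
            raise ValueError("every group needs at least 2 variants")
        if any(not 0 <= hk < 1 for hk in self.h):
            raise ValueError("heritabilities must lie in [0, 1)")
        if any(not 0 <= p <= 1 for p in self.p_neg):
            raise ValueError("p_neg must lie in [0, 1]")
        if self.trait not in ("continuous", "binary"):
            raise ValueError("trait must be 'continuous' or 'binary'")


@dataclass
class SimulatedDataset:
    """Genotypes, phenotype table and the generating truth."""

    genotypes: GenotypeMatrix
    pheno: pd.DataFrame                  # y + covariates, indexed by sample id
    true_beta: pd.Series                 # per grouped variant
    groups: pd.Series                    # variant -> group label
    singletons: list[str]
    realized_h: pd.Series                # per-group realized variance fraction
    scenario: Scenario
    seed: int


def simulate_genotypes(n: int, mafs, seed=None, ids=None) -> GenotypeMatrix:
    """Independent Hardy-Weinberg dosages: z_ij ~ Binomial(2, q_j)."""
    rng = np.random.default_rng(seed)
    q = np.asarray(mafs, float)
    if np.any(q <= 0) or np.any(q > 0.5):
        raise ValueError("minor allele frequencies must lie in (0, 0.5]")
    dos = rng.binomial(2, q, size=(n, q.size)).astype(float)
    if ids is None:
        ids = [f"v{j+1}" for j in range(q.size)]
    df = pd.DataFrame(dos, columns=list(ids),
                      index=pd.Index([f"s{i+1}" for i in range(n)],
                                     name="sample_id"))
    return GenotypeMatrix(df)


def maf_spectrum(n_common: int, n_rare: int, seed=None,
                 n_target: int = 3008) -> np.ndarray:
    """Mixed MAF spectrum: common ~ U(0.01, 0.5); rare log-uniform down to
    the singleton frequency 1/(2 n_target)."""
    if n_common < 0 or n_rare < 0:
        raise ValueError("counts must be nonnegative")
    rng = np.random.default_rng(seed)
    common = rng.uniform(0.01, 0.5, size=n_common)
    lo = np.log(1.0 / (2 * n_target))
    hi = np.log(0.01)
    rare = np.exp(rng.uniform(lo, hi, size=n_rare))
    return np.concatenate([common, rare])


def compute_beta_h(h: float, mafs, sigma_e: float) -> float:
    """Effect-size upper bound calibrated to a group heritability target."""
    if not 0 <= h < 1:
        raise ValueError("h must lie in [0, 1)")
    if sigma_e <= 0:
        raise ValueError("sigma_e must be positive")
    if h == 0:
        return 0.0
    q = np.asarray(mafs, float)
    denom = (1.0 - h) * float(np.sum(2.0 * q * (1.0 - q)))
    return float(np.sqrt(3.0 * h * sigma_e ** 2 / denom))


def simulate_effects(J: int, beta_h: float, p_neg: float, seed=None) -> np.ndarray:
    """beta_j = s_j u_j with u_j ~ U(0, beta_h), s_j = -1 w.p. p_neg else +1."""
    if not 0 <= p_neg <= 1:
        raise ValueError("p_neg must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    u = rng.uniform(0.0, beta_h, size=J)
    s = np.where(rng.random(J) < p_neg, -1.0, 1.0)
    return s * u


def simulate_phenotype(genetic_part, covariate_part, trait: str,
                       sigma_e: float, seed=None) -> np.ndarray:
    """Continuous trait = covariates + genetics + N(0, sigma_e^2); the binary
    trait labels the upper half of the continuous one as affected."""
    if sigma_e <= 0:
        raise ValueError("sigma_e must be positive")
    rng = np.random.default_rng(seed)
    y = np.asarray(covariate_part, float) + np.asarray(genetic_part, float)
    y = y + rng.normal(0.0, sigma_e, size=y.shape)
    if trait == "continuous":
        return y
    n = y.shape[0]
    order = np.argsort(y, kind="stable")
    yb = np.zeros(n)
    yb[order[n - n // 2:]] = 1.0   # top half 'affected'; prevalence 0.5 (+-1 if odd)
    return yb


def scenario_catalog(name: str, scenario: str, n: int,
                     trait: str = "continuous") -> Scenario:
    """The printed study-design configurations, by key.

    ``name`` is ``"three_groups"`` or ``"six_groups"``, ``scenario`` a letter
    (a-f / a-d), ``n`` 3008 or 1499.
    """
    table = {"three_groups": _SCENARIOS_THREE, "six_groups": _SCENARIOS_SIX}
    if name not in table:
        raise KeyError(f"unknown catalog {name!r}")
    if scenario not in table[name]:
        raise KeyError(f"unknown scenario {scenario!r} for {name}")
    if (name, n) not in SCENARIO_GROUP_SIZES:
        raise KeyError(f"no group sizes for n={n}")
    cfg = table[name][scenario]
    return Scenario(
        n=n,
        group_sizes=SCENARIO_GROUP_SIZES[(name, n)],
        h=tuple(h for h, _ in cfg),
        p_neg=tuple(p for _, p in cfg),
        trait=trait,
        common_groups=_COMMON_GROUPS[name],
        name=f"{name}:{scenario}:n={n}",
    )


def _covariate_table(n: int, rng) -> pd.DataFrame:
    race = rng.choice(["AA", "EA", "H"], size=n, p=[0.6, 0.2, 0.2])
    age = rng.uniform(18.0, 65.0, size=n)
    sex = rng.integers(0, 2, size=n).astype(float)
    bmi = rng.normal(28.0, 5.0, size=n)
    return pd.DataFrame({"race": race, "age": age, "sex": sex, "bmi": bmi})


def simulate_dataset(scenario: Scenario, seed: int) -> SimulatedDataset:
    """Draw one full replicate dataset under a scenario (pure in (scenario, seed))."""
    rng = np.random.default_rng(seed)
    n = scenario.n
    K = len(scenario.group_sizes)

    glabels, mafs, betas, vids = [], [], [], []
    realized = {}
    for k, (J, h, p_neg) in enumerate(zip(scenario.group_sizes, scenario.h,
                                          scenario.p_neg)):
        common = k in scenario.common_groups
        q = maf_spectrum(J if common else 0, 0 if common else J,
                         seed=rng, n_target=n)
        bh = compute_beta_h(h, q, scenario.sigma_e)
        b = simulate_effects(J, bh, p_neg, seed=rng)
        vg = float(np.sum(b ** 2 * 2.0 * q * (1.0 - q)))
        realized[f"G{k+1}"] = vg / (vg + scenario.sigma_e ** 2)
        mafs.append(q)
        betas.append(b)
        vids.extend(f"G{k+1}_v{j+1}" for j in range(J))
        glabels.extend([f"G{k+1}"] * J)

    singles = [f"X{i+1}" for i in range(len(scenario.singleton_mafs))]
    all_mafs = np.concatenate(mafs + [np.asarray(scenario.singleton_mafs)])
    all_ids = vids + singles
    gm = simulate_genotypes(n, all_mafs, seed=rng, ids=all_ids)
    gm.groups = pd.Series(glabels + [np.nan] * len(singles), index=all_ids)
    gm.prior_means = pd.Series(1.0, index=all_ids)

    cov = _covariate_table(n, rng)
    ce = scenario.covariate_effects
    cov_part = (
        ce.get("age", 0.0) * cov["age"].to_numpy()
        + ce.get("sex", 0.0) * cov["sex"].to_numpy()
        + ce.get("bmi", 0.0) * cov["bmi"].to_numpy()
        + ce.get("race_EA", 0.0) * (cov["race"] == "EA").to_numpy(float)
        + ce.get("race_H", 0.0) * (cov["race"] == "H").to_numpy(float)
    )
    beta = np.concatenate(betas)
    Z = gm.dosages[vids].to_numpy()
    genetic = Z @ beta
    for sid, eff in zip(singles, scenario.singleton_effects):
        genetic = genetic + eff * gm.dosages[sid].to_numpy()

    y = simulate_phenotype(genetic, cov_part, scenario.trait,
                           scenario.sigma_e, seed=rng)
    pheno = cov.copy()
    pheno.insert(0, "y", y)
    pheno.index = gm.sample_ids

    return SimulatedDataset(
        genotypes=gm,
        pheno=pheno,
        true_beta=pd.Series(beta, index=vids),
        groups=pd.Series(glabels, index=vids),
        singletons=singles,
        realized_h=pd.Series(realized),
        scenario=scenario,
        seed=seed,
    )
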