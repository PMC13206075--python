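"""Synthetic multi-dataset transcriptomic benchmark generator.

Emulates the statistical structure the downstream analysis assumes: K
independent negative-binomial (gamma-Poisson) count datasets sharing a
planted consensus differential-expression/pathway signal, a gene-set
collection containing the planted "active" sets, and knockdown/drug log2FC
profiles in which the drug profile is a noisy mean of the true targets'
knockdown profiles.  Every planted value is recorded in a
:class:`GroundTruth` so recovery can be scored exactly.

All outputs are a pure function of the configuration (including its seed):
the same :class:`SimulationConfig` always yields byte-identical data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .containers import CONTROL, TREATMENT, CountMatrix, PerturbationProfile, ValidationError
from .enrichment import GeneSetCollection

# fixed spawn keys so each component has an independent, stable stream
_KEY_SETS = 0
_KEY_COUNTS = 1
_KEY_PERTURB = 2


@dataclass
class SimulationConfig:
    """Study-design parameters for the synthetic benchmark.

    Defaults mirror the multi-model design the pipeline targets: seven
    independent datasets, a planted consensus signal carried by five of
    them (comfortably above the >=50% consensus rule), moderate
    negative-binomial dispersion, and a strong (-2) primary knockdown
    effect with mild drug noise.
    """

    n_datasets: int = 7
    n_genes: int = 2000
    n_samples_per_group: int = 6
    nb_dispersion: float = 0.1
    baseline_log_mean_range: tuple[float, float] = (3.0, 10.0)
    n_gene_sets: int = 50
    set_size_range: tuple[int, int] = (10, 40)
    n_active_sets: int = 6
    consensus_support: int = 5
    de_log2fc: float = 2.0
    true_targets: tuple[str, ...] = ("G000001", "G000002")
    kd_primary_log2fc: float = -2.0
    drug_noise_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        def positive(name):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")

        for name in ("n_datasets", "n_genes", "n_samples_per_group",
                     "nb_dispersion", "n_gene_sets"):
            positive(name)
        if self.n_samples_per_group < 2:
            raise ValidationError("n_samples_per_group must be >= 2")
        if self.n_active_sets < 0 or self.n_active_sets > self.n_gene_sets:
            raise ValidationError("n_active_sets must be in [0, n_gene_sets]")
        if not (1 <= self.consensus_support <= self.n_datasets):
            raise ValidationError("consensus_support must be in [1, n_datasets]")
        lo, hi = self.set_size_range
        if not (2 <= lo <= hi <= self.n_genes):
            raise ValidationError("set_size_range must lie within [2, n_genes]")
        lo, hi = self.baseline_log_mean_range
        if lo > hi:
            raise ValidationError("baseline_log_mean_range must be ordered")
        if self.drug_noise_sd < 0:
            raise ValidationError("drug_noise_sd must be non-negative")
        universe = set(self.gene_universe())
        for g in self.true_targets:
            if g not in universe:
                raise ValidationError(f"true_targets: {g!r} not in gene universe")

    def gene_universe(self) -> list[str]:
        return [f"G{i:06d}" for i in range(1, self.n_genes + 1)]

    def dataset_names(self) -> list[str]:
        return [f"D{k + 1}" for k in range(self.n_datasets)]

    def _rng(self, *key: int) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(self.seed, spawn_key=tuple(key))
        )


@dataclass
class GroundTruth:
    """Every planted value of one simulated study, for exact scoring."""

    active_sets: dict[str, dict] = field(default_factory=dict)
    de_genes: dict[str, dict[str, float]] = field(default_factory=dict)
    size_factors: dict[str, dict[str, float]] = field(default_factory=dict)
    true_kd_profiles: dict[str, pd.Series] = field(default_factory=dict)
    drug_profile_truth: pd.Series | None = None

    def to_json(self, path) -> None:
        payload = {
            "active_sets": self.active_sets,
            "de_genes": self.de_genes,
            "size_factors": self.size_factors,
            "true_kd_profiles": {
                g: s.to_dict() for g, s in self.true_kd_profiles.items()
            },
            "drug_profile_truth": (
                None if self.drug_profile_truth is None
                else self.drug_profile_truth.to_dict()
            ),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


def _planted_structure(config: SimulationConfig):
    """Gene sets, active-set directions/support and per-dataset DE truth.

    Shared by :func:`generate_gene_sets` and :func:`generate_counts` so the
    two outputs of one config are mutually consistent.  Active sets are
    sampled disjointly from each other so a planted gene carries exactly one
    direction.
    """
    rng = config._rng(_KEY_SETS)
    universe = np.array(config.gene_universe())
    lo, hi = config.set_size_range
    sizes = rng.integers(lo, hi + 1, size=config.n_gene_sets)

    sets: dict[str, list[str]] = {}
    active: dict[str, dict] = {}
    datasets = config.dataset_names()

    # active sets: disjoint member pools, alternating planted direction;
    # the true drug targets are planted into the first active set so the
    # knockdown/drug validation has a coherent pathway-level ground truth
    targets = [g for g in config.true_targets]
    pool = [str(g) for g in rng.permutation(universe) if g not in set(targets)]
    cursor = 0
    for i in range(config.n_active_sets):
        name = f"SET{i + 1:03d}"
        take = sizes[i] - (len(targets) if i == 0 else 0)
        take = max(take, 1)
        members = sorted((targets if i == 0 else []) + pool[cursor:cursor + take])
        cursor += take
        if len(members) < min(sizes[i], 2):
            raise ValidationError(
                "active sets exhaust the gene universe; reduce n_active_sets "
                "or set sizes"
            )
        direction = "up" if i % 2 == 0 else "down"
        carried = sorted(
            str(d) for d in
            rng.choice(datasets, size=config.consensus_support, replace=False)
        )
        sets[name] = members
        active[name] = {"direction": direction, "datasets": carried}

    for i in range(config.n_active_sets, config.n_gene_sets):
        name = f"SET{i + 1:03d}"
        sets[name] = sorted(
            str(g) for g in rng.choice(universe, size=sizes[i], replace=False)
        )

    de_genes: dict[str, dict[str, float]] = {d: {} for d in datasets}
    for name, info in active.items():
        sign = 1.0 if info["direction"] == "up" else -1.0
        for d in info["datasets"]:
            for g in sets[name]:
                de_genes[d][g] = sign * config.de_log2fc
    return sets, active, de_genes


def generate_gene_sets(config: SimulationConfig) -> GeneSetCollection:
    """Named gene-set collection whose first ``n_active_sets`` sets carry
    the planted differential signal; serializable to GMT."""
    sets, active, _ = _planted_structure(config)
    descriptions = {
        name: (f"planted {active[name]['direction']}" if name in active
               else "background")
        for name in sets
    }
    return GeneSetCollection(sets, descriptions)


def generate_counts(config: SimulationConfig) -> tuple[list[CountMatrix], GroundTruth]:
    """Draw K independent NB count datasets with the planted group effects.

    Per dataset: per-gene baseline log2 means uniform over
    ``baseline_log_mean_range``, per-sample size factors log-uniform in
    [0.5, 2], and the planted log2FC applied to the treatment group of the
    member genes of each active set in exactly ``consensus_support``
    datasets.  Counts are gamma-Poisson with a single dispersion, i.e.
    Var = mu + dispersion * mu^2.
    """
    _, active, de_genes = _planted_structure(config)
    universe = config.gene_universe()
    n = config.n_samples_per_group
    truth = GroundTruth(active_sets=active, de_genes=de_genes)

    datasets = []
    for k, dname in enumerate(config.dataset_names()):
        rng = config._rng(_KEY_COUNTS, k)
        base_log2 = rng.uniform(*config.baseline_log_mean_range, size=config.n_genes)
        sf = np.exp(rng.uniform(np.log(0.5), np.log(2.0), size=2 * n))
        samples = [f"{dname}_C{i + 1}" for i in range(n)] + \
                  [f"{dname}_T{i + 1}" for i in range(n)]
        groups = {s: (CONTROL if i < n else TREATMENT) for i, s in enumerate(samples)}

        lfc = np.zeros(config.n_genes)
        planted = de_genes[dname]
        if planted:
            idx = {g: i for i, g in enumerate(universe)}
            for g, v in planted.items():
                lfc[idx[g]] = v

        mu = 2.0 ** base_log2[:, None] * sf[None, :]
        mu[:, n:] *= 2.0 ** lfc[:, None]
        r = 1.0 / config.nb_dispersion
        counts = rng.negative_binomial(r, r / (r + mu))
        datasets.append(CountMatrix(
            pd.DataFrame(counts, index=universe, columns=samples),
            groups, name=dname,
        ))
        truth.size_factors[dname] = dict(zip(samples, sf))
    return datasets, truth


def _kd_profile(
    config: SimulationConfig,
    gene: str,
    rng: np.random.Generator,
    sets: dict[str, list[str]],
    n_modules: int = 3,
) -> pd.Series:
    """Pathway-structured downstream response to one knockdown.

    The knocked-down gene takes the primary effect; a few randomly chosen
    gene sets ("response modules") respond coherently — every member of a
    chosen module shifts in the same random direction with gene-level
    attenuation — and ~2% of other genes respond diffusely.  Coherent
    modules give the drug profile the pathway-level signal the AUROC
    analysis assumes.
    """
    universe = config.gene_universe()
    vec = pd.Series(0.0, index=universe)
    scale = abs(config.kd_primary_log2fc)

    names = rng.choice(sorted(sets), size=min(n_modules, len(sets)), replace=False)
    for name in names:
        effect = rng.choice([-1.0, 1.0]) * rng.uniform(0.5, 1.0) * scale
        members = sets[name]
        vec[members] = effect * rng.uniform(0.5, 1.0, size=len(members))

    others = [g for g in universe if g != gene]
    n_diffuse = max(1, int(round(0.02 * config.n_genes)))
    diffuse = rng.choice(others, size=min(n_diffuse, len(others)), replace=False)
    vec[diffuse] = rng.normal(0.0, scale / 4.0, size=len(diffuse))

    vec[gene] = config.kd_primary_log2fc
    return vec


def generate_perturbation_profiles(
    config: SimulationConfig,
    ground_truth: GroundTruth | None = None,
    n_decoys: int = 20,
) -> dict[str, PerturbationProfile]:
    """Drug and knockdown log2FC profiles with planted concordance structure.

    Returns one profile labeled ``"drug"`` — the arithmetic mean of the true
    targets' knockdown profiles plus N(0, drug_noise_sd) noise per gene —
    one ``"KD:<gene>"`` profile per true target, and one per decoy gene
    (decoys are generated independently of the drug).  If ``ground_truth``
    is given its knockdown/drug truth fields are filled in.
    """
    if not config.true_targets:
        raise ValidationError("true_targets must be non-empty")
    universe = config.gene_universe()
    gidx = {g: i for i, g in enumerate(universe)}
    sets, _, _ = _planted_structure(config)

    kd_truth: dict[str, pd.Series] = {}
    for g in config.true_targets:
        rng = config._rng(_KEY_PERTURB, 1, gidx[g])
        kd_truth[g] = _kd_profile(config, g, rng, sets)

    noise_rng = config._rng(_KEY_PERTURB, 0)
    drug = pd.concat(kd_truth.values(), axis=1).mean(axis=1)
    drug = drug + noise_rng.normal(0.0, config.drug_noise_sd, size=len(universe))

    decoy_rng = config._rng(_KEY_PERTURB, 2)
    eligible = [g for g in universe if g not in set(config.true_targets)]
    decoys = sorted(
        str(g) for g in decoy_rng.choice(
            eligible, size=min(n_decoys, len(eligible)), replace=False)
    )

    profiles = {"drug": PerturbationProfile("drug", drug)}
    for g in config.true_targets:
        profiles[f"KD:{g}"] = PerturbationProfile(f"KD:{g}", kd_truth[g])
    for g in decoys:
        rng = config._rng(_KEY_PERTURB, 3, gidx[g])
        profiles[f"KD:{g}"] = PerturbationProfile(
            f"KD:{g}", _kd_profile(config, g, rng, sets))

    if ground_truth is not None:
        ground_truth.true_kd_profiles = kd_truth
        ground_truth.drug_profile_truth = drug
    return profiles
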