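"""Synthetic multi-omics cohort generation with planted ground truth.

Concentrations are lognormal around class-typical means, multiplied by
group-level effects and augmented by latent particle-number factors that
induce protein-lipid correlation blocks.  Every planted effect is recorded
in a :class:`GroundTruth` so downstream stages can be scored for recovery.

The noise model maps the target coefficient of variation to the log-scale
sigma via ``sigma = sqrt(ln(1 + CV^2))``; group effects multiply the whole
feature value so planted fold changes and correlations are exact at the
population level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .core import GROUPS, GroupDesign, QuantTable, TableError

# Group sizes of the emulated cohort design.
DEFAULT_GROUP_SIZES: dict[str, int] = {
    "HC": 36, "HT": 32, "HL": 28, "HG": 29, "NL": 21,
}

# Quantifiable species per lipid class in the emulated panel.
DEFAULT_SPECIES_PER_CLASS: dict[str, int] = {
    "SM": 12, "LPC": 9, "LPE": 4, "CE": 22, "PC": 22, "PE": 20,
    "CER": 6, "HCER": 4, "FFA": 23, "DAG": 17, "TAG": 435,
}

# Reference-group lipid class total concentrations (nmol/mL); per-species
# base means are the class total divided by the species count, jittered.
CLASS_MEAN_REFERENCE: dict[str, float] = {
    "CE": 3902.51, "CER": 7.55, "DAG": 43.65, "FFA": 775.00, "HCER": 3.93,
    "LPC": 637.43, "LPE": 5.67, "PC": 1565.61, "PE": 66.83, "SM": 473.00,
    "TAG": 1272.10, "LCER": 4.0,
}

# Reference-group mean concentrations (nmol/L) of the 20-protein panel.
PROTEIN_MEAN_REFERENCE: dict[str, float] = {
    "apoA1": 43776.14, "AACT": 27568.85, "apoA2": 39002.86, "apoA4": 1425.91,
    "apoB": 1220.63, "apoC1": 8227.14, "apoC2": 2998.99, "apoC3": 8056.58,
    "apoD": 2322.35, "apoE": 1149.86, "apoM": 910.80, "CETP": 33.36,
    "HP": 17136.29, "LCAT": 76.81, "apo(a)": 82.53, "PLTP": 76.33,
    "PON1": 1644.84, "SAA1": 472.28, "SAA4": 1713.41, "TF": 1230.71,
}


def cv_to_sigma(cv: float) -> float:
    """Log-scale sigma of a lognormal with the given coefficient of variation."""
    return math.sqrt(math.log1p(cv * cv))


@dataclass(frozen=True)
class Effect:
    """Multiplicative mean shift of a feature set in one group."""

    group: str
    features: tuple[str, ...]
    factor: float

    def __post_init__(self) -> None:
        if self.factor <= 0:
            raise TableError("effect factors must be positive")


@dataclass
class LatentFactor:
    """Shared particle-number-like factor driving correlated blocks.

    ``loading`` maps feature -> nonnegative additive weight on the natural
    concentration scale; ``group_scale`` multiplies the factor value per
    group (default 1).  ``cv`` is the factor's own coefficient of variation.
    """

    name: str
    loading: dict[str, float]
    group_scale: dict[str, float] = field(default_factory=dict)
    cv: float = 0.15

    def __post_init__(self) -> None:
        if any(w < 0 for w in self.loading.values()):
            raise TableError("latent loadings must be nonnegative")
        if any(s <= 0 for s in self.group_scale.values()):
            raise TableError("group scales must be positive")

    def scale_for(self, group: str) -> float:
        return float(self.group_scale.get(group, 1.0))


def make_latent_factor(
    name: str,
    features: Sequence[str],
    base_means: Mapping[str, float],
    target_r: float,
    noise_cv: float,
    group_scale: Optional[Mapping[str, float]] = None,
) -> LatentFactor:
    """Latent factor whose loadings plant pairwise Pearson r ~= target_r.

    With loading a*m_f on each feature and factor CV equal to the noise CV,
    the induced pairwise correlation is a^2 / (1 + a^2); solving gives
    a = sqrt(r / (1 - r)).
    """
    if not (0 < target_r < 1):
        raise TableError("target_r must lie in (0, 1)")
    a = math.sqrt(target_r / (1.0 - target_r))
    loading = {f: a * float(base_means[f]) for f in features}
    return LatentFactor(
        name=name,
        loading=loading,
        group_scale=dict(group_scale or {}),
        cv=noise_cv,
    )


@dataclass
class SyntheticConfig:
    """Full parameterization of one synthetic cohort."""

    group_sizes: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_SIZES)
    )
    n_species_per_class: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_SPECIES_PER_CLASS)
    )
    n_proteins: int = 20
    effects: list[Effect] = field(default_factory=list)
    latent_factors: list[LatentFactor] = field(default_factory=list)
    cv_target: float = 0.15
    missing_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 2 for n in self.group_sizes.values()):
            raise TableError("every group needs at least 2 samples")
        if not (0 <= self.cv_target < 1):
            raise TableError("cv_target must lie in [0, 1)")
        if not (0 <= self.missing_rate < 0.3):
            raise TableError("missing_rate must lie in [0, 0.3)")


@dataclass
class GroundTruth:
    """Planted signals of a generated cohort."""

    differential_up: dict[str, set[str]]     # group -> features shifted up
    differential_down: dict[str, set[str]]   # group -> features shifted down
    correlated_pairs: dict[str, set[tuple[str, str]]]  # group -> (protein, lipid)
    informative_predictors: set[str]

    def to_jsonable(self) -> dict:
        return {
            "differential_up": {g: sorted(s) for g, s in self.differential_up.items()},
            "differential_down": {
                g: sorted(s) for g, s in self.differential_down.items()
            },
            "correlated_pairs": {
                g: sorted(list(p) for p in pairs)
                for g, pairs in self.correlated_pairs.items()
            },
            "informative_predictors": sorted(self.informative_predictors),
        }


# ---------------------------------------------------------------------------
# feature panel construction
# ---------------------------------------------------------------------------

_SINGLE_CHAIN = ("CE", "CER", "FFA", "HCER", "LCER", "LPC", "LPE", "SM")
_TWO_CHAIN = ("PC", "PE", "DAG")

_CARBONS = (14, 16, 18, 20, 22, 24, 12, 15, 17, 26, 13, 19, 21, 23)
_CHAINS = (
    (16, 0), (18, 1), (18, 2), (18, 0), (20, 4), (16, 1), (22, 6),
    (20, 3), (22, 4), (14, 0), (15, 0), (17, 0), (17, 1), (20, 0),
)
_TAG_FAS = ((16, 0), (18, 1), (18, 2), (14, 0), (20, 4), (18, 0), (12, 0))


def _single_chain_names(cls: str, n: int) -> list[str]:
    names: list[str] = []
    for c in _CARBONS:
        for d in range(0, 7):
            names.append(f"{cls}({c}:{d})")
            if len(names) == n:
                return names
    raise TableError(f"cannot generate {n} names for class {cls}")


def _two_chain_names(cls: str, n: int) -> list[str]:
    names: list[str] = []
    seen: set[str] = set()
    for i, ch1 in enumerate(_CHAINS):
        for ch2 in _CHAINS[i:]:
            for prefix in ("", "P-") if cls == "PE" else ("",):
                name = f"{cls}({prefix}{ch1[0]}:{ch1[1]}/{ch2[0]}:{ch2[1]})"
                if name not in seen:
                    seen.add(name)
                    names.append(name)
                if len(names) == n:
                    return names
    raise TableError(f"cannot generate {n} names for class {cls}")


def _tag_names(n: int) -> list[str]:
    names: list[str] = []
    for total_c in range(40, 61):
        for total_d in range(0, 10):
            for fa in _TAG_FAS:
                if fa[1] > total_d or fa[0] >= total_c:
                    continue
                names.append(f"TAG({total_c}:{total_d}-FA{fa[0]}:{fa[1]})")
                if len(names) == n:
                    return names
    raise TableError(f"cannot generate {n} TAG names")


def make_feature_panel(config: SyntheticConfig) -> pd.DataFrame:
    """Feature metadata (layer, lipid_class, units) for a config's panel."""
    rows = {}
    for cls in sorted(config.n_species_per_class):
        n = config.n_species_per_class[cls]
        if n <= 0:
            continue
        if cls == "TAG":
            names = _tag_names(n)
        elif cls in _TWO_CHAIN:
            names = _two_chain_names(cls, n)
        elif cls in _SINGLE_CHAIN:
            names = _single_chain_names(cls, n)
        else:
            raise TableError(f"unknown lipid class {cls!r}")
        for name in names:
            rows[name] = {"layer": "lipid", "lipid_class": cls, "units": "nmol/mL"}
    protein_names = list(PROTEIN_MEAN_REFERENCE)
    for i in range(config.n_proteins):
        name = (
            protein_names[i]
            if i < len(protein_names)
            else f"protein{i + 1:02d}"
        )
        rows[name] = {"layer": "protein", "lipid_class": "", "units": "nmol/L"}
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("feature_id")


def base_means(config: SyntheticConfig) -> pd.Series:
    """Deterministic per-feature base (reference-group) mean concentrations.

    Lipid species split their class total with a mild multiplicative
    spread; proteins use their panel reference means.
    """
    meta = make_feature_panel(config)
    rng = np.random.default_rng([config.seed, 101])
    means = {}
    for cls in sorted(config.n_species_per_class):
        feats = meta.index[(meta["layer"] == "lipid") & (meta["lipid_class"] == cls)]
        if len(feats) == 0:
            continue
        class_total = CLASS_MEAN_REFERENCE.get(cls, 10.0)
        spread = np.exp(rng.normal(0.0, 0.5, size=len(feats)))
        spread = spread / spread.sum()
        for f, w in zip(feats, spread):
            means[f] = class_total * float(w)
    protein_defaults = list(PROTEIN_MEAN_REFERENCE.items())
    prot_feats = meta.index[meta["layer"] == "protein"]
    for i, f in enumerate(prot_feats):
        means[f] = (
            protein_defaults[i][1] if i < len(protein_defaults) else 1000.0
        )
    return pd.Series(means).reindex(meta.index)


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def _make_design(config: SyntheticConfig) -> GroupDesign:
    assignment = {}
    ordered = [g for g in GROUPS if g in config.group_sizes]
    ordered += sorted(set(config.group_sizes) - set(GROUPS))
    for g in ordered:
        for i in range(config.group_sizes[g]):
            assignment[f"{g}_{i + 1:02d}"] = g
    reference = "NL" if "NL" in config.group_sizes else ordered[-1]
    return GroupDesign(pd.Series(assignment), reference=reference)


def _shift_matrix(
    config: SyntheticConfig, design: GroupDesign, features: pd.Index
) -> pd.DataFrame:
    """Per (feature, group) multiplicative shift from the effect table."""
    shifts = pd.DataFrame(1.0, index=features, columns=design.groups)
    for eff in config.effects:
        missing = [f for f in eff.features if f not in features]
        if missing:
            raise TableError(f"effect references unknown features: {missing}")
        if eff.group not in shifts.columns:
            raise TableError(f"effect references unknown group {eff.group!r}")
        shifts.loc[list(eff.features), eff.group] *= eff.factor
    return shifts


def planted_correlation(
    config: SyntheticConfig,
    means: pd.Series,
    f: str,
    g: str,
    group: str,
) -> float:
    """Population Pearson r between two features implied by the factor model."""
    sigma_noise = cv_to_sigma(config.cv_target)
    noise_var = {
        feat: (float(means[feat]) * config.cv_target) ** 2 for feat in (f, g)
    }
    cov = 0.0
    var_extra = {f: 0.0, g: 0.0}
    for factor in config.latent_factors:
        lf = factor.loading.get(f, 0.0)
        lg = factor.loading.get(g, 0.0)
        s = factor.scale_for(group)
        fac_var = (s * factor.cv) ** 2
        cov += lf * lg * fac_var
        var_extra[f] += lf * lf * fac_var
        var_extra[g] += lg * lg * fac_var
    denom = math.sqrt(
        (noise_var[f] + var_extra[f]) * (noise_var[g] + var_extra[g])
    )
    if denom == 0 or sigma_noise == 0:
        return 0.0 if cov == 0 else 1.0
    return cov / denom


def _ground_truth(
    config: SyntheticConfig,
    design: GroupDesign,
    meta: pd.DataFrame,
    means: pd.Series,
    r_threshold: float = 0.5,
) -> GroundTruth:
    up: dict[str, set[str]] = {g: set() for g in design.non_reference_groups}
    down: dict[str, set[str]] = {g: set() for g in design.non_reference_groups}
    shifts = _shift_matrix(config, design, meta.index)
    ref = shifts[design.reference]
    for g in design.non_reference_groups:
        ratio = shifts[g] / ref
        up[g] = set(shifts.index[ratio > 1.0])
        down[g] = set(shifts.index[ratio < 1.0])
    proteins = list(meta.index[meta["layer"] == "protein"])
    pairs: dict[str, set[tuple[str, str]]] = {}
    loaded = sorted(
        {f for fac in config.latent_factors for f, w in fac.loading.items() if w > 0}
    )
    loaded_p = [f for f in loaded if f in set(proteins)]
    loaded_l = [f for f in loaded if f not in set(proteins)]
    for g in design.groups:
        found = set()
        for p in loaded_p:
            for l in loaded_l:
                if abs(planted_correlation(config, means, p, l, g)) >= r_threshold:
                    found.add((p, l))
        pairs[g] = found
    informative = {f for eff in config.effects if eff.factor != 1.0
                   for f in eff.features}
    return GroundTruth(
        differential_up=up,
        differential_down=down,
        correlated_pairs=pairs,
        informative_predictors=informative,
    )


def generate_cohort(
    config: SyntheticConfig,
) -> tuple[QuantTable, GroupDesign, GroundTruth]:
    """Generate a cohort table, its design and the planted ground truth.

    Deterministic under a fixed config seed.  Missingness (MCAR at
    ``config.missing_rate``) is injected after signal generation.
    """
    design = _make_design(config)
    meta = make_feature_panel(config)
    means = base_means(config)
    shifts = _shift_matrix(config, design, meta.index)

    n_samples = design.n_samples
    n_features = len(meta)
    sigma = cv_to_sigma(config.cv_target)
    rng = np.random.default_rng([config.seed, 202])

    # multiplicative lognormal noise with exact mean 1
    noise = np.exp(
        rng.normal(0.0, sigma, size=(n_samples, n_features)) - sigma**2 / 2.0
    )
    base = means.to_numpy(dtype=float)[None, :] * noise

    # additive latent-factor contributions (particle-number interpretation)
    samples = list(design.assignment.index)
    group_of = design.assignment
    for factor in config.latent_factors:
        sigma_f = cv_to_sigma(factor.cv)
        scores = np.exp(
            rng.normal(0.0, sigma_f, size=n_samples) - sigma_f**2 / 2.0
        )
        scales = np.array([factor.scale_for(group_of[s]) for s in samples])
        scores = scores * scales
        loadings = np.array(
            [factor.loading.get(f, 0.0) for f in meta.index], dtype=float
        )
        base = base + scores[:, None] * loadings[None, :]

    # group-level multiplicative shifts applied to the whole value so that
    # planted fold changes survive the latent contributions exactly
    shift_arr = np.array(
        [shifts.loc[:, group_of[s]].to_numpy(dtype=float) for s in samples]
    )
    values = base * shift_arr

    table = QuantTable(
        pd.DataFrame(values, index=samples, columns=meta.index), meta
    )
    if config.missing_rate > 0:
        table = inject_missingness(
            table, config.missing_rate, seed=[config.seed, 303]
        )
    truth = _ground_truth(config, design, meta, means)
    return table, design, truth


def generate_qc_replicates(config: SyntheticConfig, n_reps: int) -> QuantTable:
    """Pure-noise QC replicate table around the panel base means.

    Replicate CVs concentrate near ``config.cv_target``; requires at least
    3 replicates.
    """
    if n_reps < 3:
        raise TableError("need at least 3 QC replicates")
    meta = make_feature_panel(config)
    means = base_means(config)
    sigma = cv_to_sigma(config.cv_target)
    rng = np.random.default_rng([config.seed, 404])
    noise = np.exp(
        rng.normal(0.0, sigma, size=(n_reps, len(meta))) - sigma**2 / 2.0
    )
    values = means.to_numpy(dtype=float)[None, :] * noise
    index = [f"QC_{i + 1:02d}" for i in range(n_reps)]
    return QuantTable(pd.DataFrame(values, index=index, columns=meta.index), meta)


def demo_config(seed: int = 0, full_panel: bool = False) -> SyntheticConfig:
    """Small ready-made cohort config with planted effects and one factor.

    Uses a reduced panel (unless ``full_panel``) so demo pipeline runs stay
    fast; plants class-typical group shifts and one particle-number factor
    linking apoB-like proteins to a TAG block.
    """
    n_species = (
        dict(DEFAULT_SPECIES_PER_CLASS)
        if full_panel
        else {"SM": 6, "LPC": 5, "LPE": 4, "CE": 8, "PC": 8, "PE": 6,
              "CER": 4, "HCER": 3, "FFA": 6, "DAG": 5, "TAG": 25}
    )
    config = SyntheticConfig(
        n_species_per_class=n_species, n_proteins=12, seed=seed,
        missing_rate=0.02,
    )
    meta = make_feature_panel(config)
    by_class = {
        cls: list(meta.index[meta["lipid_class"] == cls])
        for cls in n_species
    }
    proteins = list(meta.index[meta["layer"] == "protein"])
    effects = [
        Effect("HL", tuple(by_class["TAG"][:10]), 2.5),
        Effect("HT", tuple(by_class["TAG"][:10]), 2.4),
        Effect("HC", tuple(by_class["CE"][:5]), 1.7),
        Effect("HL", tuple(by_class["CE"][:5]), 1.6),
        Effect("HG", tuple(by_class["DAG"][:3]), 1.5),
        Effect("HG", tuple(by_class["LPC"][:2]), 0.6),
        Effect("HC", tuple(proteins[:2]), 1.4),
        Effect("HG", tuple(proteins[2:4]), 1.5),
    ]
    config.effects = effects
    means = base_means(config)
    factor_feats = proteins[:2] + by_class["TAG"][:6]
    config.latent_factors = [
        make_latent_factor(
            "apoB_particles", factor_feats, means, target_r=0.8,
            noise_cv=config.cv_target,
        )
    ]
    return config


def inject_missingness(
    table: QuantTable, rate: float, seed: int | Sequence[int] = 0
) -> QuantTable:
    """Blank each cell independently with probability ``rate`` (MCAR)."""
    if not (0 <= rate < 1):
        raise TableError("missing rate must lie in [0, 1)")
    if rate == 0:
        return table.copy()
    rng = np.random.default_rng(seed)
    mask = rng.random(table.values.shape) < rate
    vals = table.values.mask(mask)
    return QuantTable(vals, table.feature_meta.copy())
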