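"""Synthetic multi-population landmark datasets with planted effects.

The generator emulates the statistical structure the analysis assumes: a
bilaterally symmetric template configuration deformed by covariate effects
(sex, age class, captivity, temperature and allometry) along fixed symmetric
deformation directions, population-level random deviations of size and
shape, landmark noise split into symmetric and asymmetric parts, and
similarity-transform nuisance (random rotation and translation, scale
carrying the size signal).

Real shape covariance is strongly anisotropic — a handful of PCs carry most
of the variance — so individual "biological" variation is low-rank: latent
deviations along ``n_latent`` fixed orthonormal symmetric directions with
geometrically decaying scales, the first of which are the effect directions
themselves.  Isotropic symmetric noise on top models digitizing error.

Effect sizes are dimensionless: an effect of 0.4 displaces shape along its
direction by 0.4 of that direction's natural (latent) standard deviation
per standard deviation of the covariate.  Effects are planted in
landmark-coordinate space (PCs are data-dependent);
``truth_in_pc_space`` projects the planted coefficients through a fitted PCA
so that recovery by the mixed model is testable on the model's own scale.

Everything is drawn from one seeded generator, so a config reproduces its
dataset bit for bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional
import warnings

import numpy as np
import pandas as pd

from .landmark_io import (
    LandmarkConfiguration,
    packaged_population_table,
    write_landmarks,
)
from .scheme import LandmarkScheme, mandible_scheme
from .shape_space import ShapePCA
from .superimpose import _kabsch, _unit, centroid_size, reflect_relabel

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "SyntheticDataset",
    "packaged_template",
    "effect_directions",
    "generate",
    "truth_in_pc_space",
    "true_standardized_size_effects",
]

_ISLAND_POPULATIONS = {"Yakushima", "Shodoshima", "Miyajima", "Kinkazan"}

#: effects with a shape direction, in planting order
_SHAPE_EFFECTS = ("allometry", "sex_shape", "age_shape", "captivity_shape", "temperature_shape")
#: map shape-effect key -> metadata column ('size' handled separately)
_SHAPE_COVARIATE = {
    "sex_shape": "sex",
    "age_shape": "age_class",
    "captivity_shape": "captivity",
    "temperature_shape": "temperature",
}


def packaged_template(scheme: Optional[LandmarkScheme] = None) -> np.ndarray:
    """The packaged synthetic mandible-like template (k x 3, mm): exactly
    reflect-relabel symmetric, midline landmarks on the x = 0 plane."""
    scheme = scheme or mandible_scheme()
    ref = resources.files("mandmorph.data").joinpath("template_mandible_synthetic.csv")
    with resources.as_file(ref) as p:
        df = pd.read_csv(p)
    df = df.set_index("landmark").loc[list(scheme.names)]
    return df[["x", "y", "z"]].to_numpy(dtype=float)


@dataclass
class GeneratorConfig:
    """Stated world of the generator.

    With ``population_table=None`` and ``use_packaged_design=True`` the
    design replicates the packaged 23-population sampling table (uneven
    sizes, captivity confounded with a subset of populations).  Otherwise a
    uniform design of ``n_populations`` x ``n_per_population`` is built with
    ``captive_fraction`` of the populations captive.
    """

    n_populations: int = 23
    n_per_population: int = 8
    use_packaged_design: bool = True
    population_table: Optional[pd.DataFrame] = None
    captive_fraction: float = 0.4
    sex_ratio: float = 76 / 177  # probability male
    adult_fraction: float = 152 / 177
    founder_fraction: float = 39 / 93  # captives that are founders
    effect_sizes: dict = field(
        default_factory=lambda: {
            "sex_size": 0.7,
            "age_size": 0.2,
            "allometry": 0.5,
            "sex_shape": 0.5,
            "age_shape": 0.2,
            "captivity_shape": 0.4,
            "temperature_shape": 0.0,
        }
    )
    pop_sd_size: float = 0.03
    size_noise_sd: float = 0.05
    pop_sd_shape: float = 0.5  # mm, per symmetric direction
    n_latent: int = 10  # rank of the biological shape covariance
    latent_sd_max: float = 2.5  # mm, largest latent direction sd
    latent_sd_min: float = 0.8  # mm, smallest latent direction sd
    landmark_noise_sd: float = 0.3  # mm, isotropic digitizing noise
    asymmetry_sd: float = 0.3  # mm
    nuisance: bool = True
    seed: int = 0
    direction_seed: int = 1234  # directions are part of the stated world

    def __post_init__(self) -> None:
        for key, val in self.effect_sizes.items():
            if key not in dict(_default_effects()):
                raise KeyError(f"unknown effect {key!r}")
        merged = dict(_default_effects())
        merged.update(self.effect_sizes)
        self.effect_sizes = merged
        if self.n_latent < len(_SHAPE_EFFECTS):
            raise ValueError(
                f"n_latent must be >= {len(_SHAPE_EFFECTS)} (one slot per effect)"
            )
        for name in ("pop_sd_size", "size_noise_sd", "pop_sd_shape",
                     "latent_sd_max", "latent_sd_min",
                     "landmark_noise_sd", "asymmetry_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def latent_sds(self) -> np.ndarray:
        """Geometrically decaying latent-direction scales (mm)."""
        if self.latent_sd_max <= 0.0:
            return np.zeros(self.n_latent)
        lo = max(self.latent_sd_min, 1e-12)
        return np.geomspace(self.latent_sd_max, lo, self.n_latent)


def _default_effects() -> list[tuple[str, float]]:
    return [
        ("sex_size", 0.7),
        ("age_size", 0.2),
        ("allometry", 0.5),
        ("sex_shape", 0.5),
        ("age_shape", 0.2),
        ("captivity_shape", 0.4),
        ("temperature_shape", 0.0),
    ]


@dataclass
class GroundTruth:
    """Planted parameters of one generated dataset.

    ``gamma_shape`` maps model predictor names (size, sex, age_class,
    captivity, temperature) to flattened coordinate-space coefficient
    vectors per raw covariate unit, in the template's mm frame;
    ``gamma_size`` maps size-model predictors to log-size coefficients per
    raw unit.  ``directions`` are the unit deformation vectors.
    """

    metadata: pd.DataFrame
    gamma_shape: dict[str, np.ndarray]
    gamma_size: dict[str, float]
    directions: dict[str, np.ndarray]
    template: np.ndarray
    template_size: float
    seed: int
    config: GeneratorConfig

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "template_size": self.template_size,
            "gamma_size": self.gamma_size,
            "gamma_shape": {k: v.tolist() for k, v in self.gamma_shape.items()},
            "directions": {k: v.tolist() for k, v in self.directions.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


@dataclass
class SyntheticDataset:
    configs: list[LandmarkConfiguration]
    metadata: pd.DataFrame
    truth: GroundTruth

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_landmarks(self.configs, outdir / "landmarks.csv", layout="long")
        self.metadata.to_csv(outdir / "metadata.csv", index=False)
        self.truth.to_json(outdir / "truth.json")


# ---------------------------------------------------------------------------
# deformation directions
# ---------------------------------------------------------------------------


def _similarity_basis(template: np.ndarray) -> np.ndarray:
    """Orthonormal basis (rows) of the similarity-transform subspace at the
    template: d translations, rotation generators, and uniform scaling."""
    k, d = template.shape
    T = template - template.mean(axis=0)
    vecs = []
    for j in range(d):
        v = np.zeros((k, d))
        v[:, j] = 1.0
        vecs.append(v.reshape(-1))
    if d == 3:
        gens = [
            np.array([[0, -1, 0], [1, 0, 0], [0, 0, 0]], float),
            np.array([[0, 0, 1], [0, 0, 0], [-1, 0, 0]], float),
            np.array([[0, 0, 0], [0, 0, -1], [0, 1, 0]], float),
        ]
    else:
        gens = [np.array([[0, -1], [1, 0]], float)]
    for A in gens:
        vecs.append((T @ A.T).reshape(-1))
    vecs.append(T.reshape(-1))
    M = np.array(vecs)
    # orthonormalize (rows)
    Q, _ = np.linalg.qr(M.T)
    return Q.T[: M.shape[0]]


def _symmetrize_flat(v: np.ndarray, scheme: LandmarkScheme, shape: tuple[int, int]) -> np.ndarray:
    arr = v.reshape(shape)
    return 0.5 * (arr + reflect_relabel(arr, scheme)).reshape(-1)


def effect_directions(
    template: np.ndarray, scheme: LandmarkScheme, names=_SHAPE_EFFECTS, seed: int = 1234
) -> dict[str, np.ndarray]:
    """Mutually orthogonal unit deformation vectors: symmetric, and
    orthogonal to the similarity-transform subspace at the template."""
    k, d = template.shape
    rng = np.random.default_rng(seed)
    sim = _similarity_basis(template)
    chosen: list[np.ndarray] = []
    out: dict[str, np.ndarray] = {}
    for name in names:
        for _ in range(100):
            v = rng.standard_normal(k * d)
            v = _symmetrize_flat(v, scheme, (k, d))
            v -= sim.T @ (sim @ v)
            for c in chosen:
                v -= (c @ v) * c
            norm = np.linalg.norm(v)
            if norm > 1e-6:
                v /= norm
                break
        else:  # pragma: no cover
            raise RuntimeError("could not build an independent direction")
        chosen.append(v)
        out[name] = v
    return out


# ---------------------------------------------------------------------------
# design / covariates
# ---------------------------------------------------------------------------


def _design_table(config: GeneratorConfig) -> pd.DataFrame:
    if config.population_table is not None:
        return config.population_table.copy()
    if config.use_packaged_design:
        return packaged_population_table()
    P = config.n_populations
    n_captive = max(1, round(config.captive_fraction * P)) if config.captive_fraction > 0 else 0
    lats = np.linspace(41.5, 30.5, P)
    env = ["wild"] * P
    # interleave captive populations across the latitude range
    captive_idx = np.linspace(0, P - 1, n_captive).round().astype(int) if n_captive else []
    for i in captive_idx:
        env[int(i)] = "captive"
    half = config.n_per_population // 2
    return pd.DataFrame(
        {
            "population": [f"pop{i:02d}" for i in range(P)],
            "environment": env,
            "latitude": lats,
            "longitude": np.linspace(141.0, 130.5, P),
            "n_female": [config.n_per_population - half] * P,
            "n_male": [half] * P,
            "n_young": [max(0, round((1 - config.adult_fraction) * config.n_per_population))] * P,
        }
    )


def _population_climate(design: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    """Population-level temperature/precipitation correlated with latitude
    (|r| around 0.7-0.8, mirroring real ecogeographical covariates)."""
    lat = design["latitude"].to_numpy(float)
    temp = 15.8 - 0.85 * (lat - 35.0) + rng.normal(0.0, 1.5, len(lat))
    prec = 1600.0 - 40.0 * (lat - 35.0) + rng.normal(0.0, 70.0, len(lat))
    out = design.copy()
    out["temperature"] = np.round(temp, 2)
    out["precipitation"] = np.round(prec, 0)
    return out


def _specimen_covariates(config: GeneratorConfig, rng: np.random.Generator) -> pd.DataFrame:
    design = _population_climate(_design_table(config), rng)
    rows = []
    idx = 0
    for _, pop in design.iterrows():
        total = int(pop["n_female"] + pop["n_male"])
        sexes = np.array([1] * int(pop["n_male"]) + [0] * int(pop["n_female"]))
        rng.shuffle(sexes)
        young = np.zeros(total, dtype=int)
        n_young = int(pop["n_young"])
        if n_young:
            young[rng.choice(total, size=min(n_young, total), replace=False)] = 1
        env = pop["environment"]
        island = int(pop["population"] in _ISLAND_POPULATIONS)
        for j in range(total):
            if env == "wild":
                captive = False
            elif env == "captive":
                captive = True
            else:  # mixed locality
                captive = bool(rng.random() < 0.5)
            if captive:
                captivity = 1 if rng.random() < config.founder_fraction else 2
                age_years = float(np.clip(rng.normal(14.0, 5.7), 6.4, 29.5))
                generation = 0 if captivity == 1 else int(rng.integers(1, 5))
            else:
                captivity, age_years, generation = 0, np.nan, np.nan
            rows.append(
                {
                    "specimen_id": f"spec{idx:04d}",
                    "sex": int(sexes[j]),
                    "age_class": int(1 - young[j]),
                    "captivity": captivity,
                    "population": pop["population"],
                    "latitude": float(pop["latitude"]),
                    "longitude": float(pop["longitude"]),
                    "temperature": float(pop["temperature"]),
                    "precipitation": float(pop["precipitation"]),
                    "island": island,
                    "age_years": age_years,
                    "generation": generation,
                }
            )
            idx += 1
    return pd.DataFrame(rows)


def _zscore(x: np.ndarray) -> tuple[np.ndarray, float]:
    """Z-score against the realized sample; constant columns map to zero."""
    sd = x.std(ddof=1)
    if sd == 0.0 or not np.isfinite(sd):
        return np.zeros_like(x), 0.0
    return (x - x.mean()) / sd, float(sd)


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def generate(config: GeneratorConfig, scheme: Optional[LandmarkScheme] = None) -> SyntheticDataset:
    """Generate one synthetic dataset with its ground-truth manifest."""
    scheme = scheme or mandible_scheme()
    template = packaged_template(scheme)
    k, d = template.shape
    S0 = centroid_size(template)
    lam = config.landmark_noise_sd

    rng = np.random.default_rng(config.seed)
    meta = _specimen_covariates(config, rng)
    n = len(meta)
    pops = meta["population"].to_numpy()
    pop_labels = list(dict.fromkeys(pops))
    pop_index = np.array([pop_labels.index(p) for p in pops])
    G = len(pop_labels)

    latent_names = list(_SHAPE_EFFECTS) + [
        f"extra{j}" for j in range(config.n_latent - len(_SHAPE_EFFECTS))
    ]
    directions = effect_directions(
        template, scheme, names=latent_names, seed=config.direction_seed
    )
    latent_sd = dict(zip(latent_names, config.latent_sds()))
    e = config.effect_sizes

    # --- size: log centroid size
    z_sex, sd_sex = _zscore(meta["sex"].to_numpy(float))
    z_age, sd_age = _zscore(meta["age_class"].to_numpy(float))
    u_size = rng.normal(0.0, config.pop_sd_size, G)
    eps_size = rng.normal(0.0, config.size_noise_sd, n)
    log_cs = (
        np.log(S0)
        + e["sex_size"] * config.size_noise_sd * z_sex
        + e["age_size"] * config.size_noise_sd * z_age
        + u_size[pop_index]
        + eps_size
    )

    gamma_size = {
        "sex": e["sex_size"] * config.size_noise_sd / sd_sex if sd_sex else 0.0,
        "age_class": e["age_size"] * config.size_noise_sd / sd_age if sd_age else 0.0,
    }

    # --- shape: template + planted effects + population deviation + noise
    z_size, sd_logcs = _zscore(log_cs)
    covariate_z = {"allometry": (z_size, sd_logcs)}
    for key, col in _SHAPE_COVARIATE.items():
        covariate_z[key] = _zscore(meta[col].to_numpy(float))

    flat = np.tile(template.reshape(-1), (n, 1))
    gamma_shape: dict[str, np.ndarray] = {}
    for key in _SHAPE_EFFECTS:
        z, sd = covariate_z[key]
        contribution = e[key] * latent_sd[key]
        flat += np.outer(z, contribution * directions[key])
        pred = "size" if key == "allometry" else _SHAPE_COVARIATE[key]
        gamma_shape[pred] = (
            (contribution / sd) * directions[key] if sd else np.zeros(k * d)
        )

    # low-rank biological variation along the latent directions
    for name in latent_names:
        s = latent_sd[name]
        if s > 0:
            flat += np.outer(rng.normal(0.0, s, n), directions[name])

    if config.pop_sd_shape > 0:
        pop_dev = rng.normal(0.0, config.pop_sd_shape, (G, k * d))
        pop_dev = np.stack(
            [_symmetrize_flat(v, scheme, (k, d)) for v in pop_dev]
        )
        flat += pop_dev[pop_index]
    if lam > 0:
        noise = rng.normal(0.0, lam, (n, k * d))
        flat += np.stack([_symmetrize_flat(v, scheme, (k, d)) for v in noise])
    if config.asymmetry_sd > 0:
        noise = rng.normal(0.0, config.asymmetry_sd, (n, k * d))
        sym = np.stack([_symmetrize_flat(v, scheme, (k, d)) for v in noise])
        flat += noise - sym  # antisymmetric part only

    # --- express size, apply nuisance transforms
    configs = []
    for i in range(n):
        coords = flat[i].reshape(k, d)
        coords = coords - coords.mean(axis=0)
        coords = coords * (np.exp(log_cs[i]) / centroid_size(coords))
        if config.nuisance:
            Q, _ = np.linalg.qr(rng.standard_normal((d, d)))
            if np.linalg.det(Q) < 0:
                Q[:, -1] = -Q[:, -1]
            coords = coords @ Q + rng.uniform(-50.0, 50.0, d)
        configs.append(
            LandmarkConfiguration(meta["specimen_id"].iloc[i], coords, scheme)
        )

    truth = GroundTruth(
        metadata=meta,
        gamma_shape=gamma_shape,
        gamma_size=gamma_size,
        directions=directions,
        template=template,
        template_size=S0,
        seed=config.seed,
        config=config,
    )
    return SyntheticDataset(configs=configs, metadata=meta, truth=truth)


# ---------------------------------------------------------------------------
# truth in the fitted model's coordinates
# ---------------------------------------------------------------------------


def truth_in_pc_space(
    truth: GroundTruth,
    pca: ShapePCA,
    m: int,
    data: pd.DataFrame,
) -> pd.DataFrame:
    """Planted coefficients expressed as standardized PC-space effects.

    The planted coordinate-space coefficients (template mm frame) are mapped
    into the superimposed frame (rotation from the unit template onto the
    PCA consensus, scale 1/template_size), projected through the first ``m``
    loadings, and standardized with the realized covariate and score
    standard deviations from ``data`` — the scale on which the mixed model
    is fitted.  Warns when the retained PC basis spans less than 95% of a
    planted direction's norm.
    """
    unit_template = _unit(truth.template)
    R = _kabsch(unit_template, _unit(pca.consensus.reshape(truth.template.shape)))
    k, d = truth.template.shape
    load = pca.loadings[:m]  # m x (k*d)
    score_sd = pca.scores[:, :m].std(axis=0, ddof=1)

    rows = {}
    for pred, gamma in truth.gamma_shape.items():
        gamma_aligned = ((gamma.reshape(k, d) @ R) / truth.template_size).reshape(-1)
        gnorm = np.linalg.norm(gamma_aligned)
        proj = load @ gamma_aligned  # m
        if gnorm > 0 and np.linalg.norm(proj) < 0.95 * gnorm:
            warnings.warn(
                f"retained PCs span only "
                f"{np.linalg.norm(proj) / gnorm:.1%} of the planted "
                f"{pred!r} direction",
                stacklevel=2,
            )
        x_sd = data[pred].std(ddof=1)  # 'size' = log centroid size column
        rows[pred] = proj * (x_sd / score_sd)
    out = pd.DataFrame(rows).T
    out.columns = [f"PC{j + 1}" for j in range(m)]
    return out


def true_standardized_size_effects(truth: GroundTruth, log_cs: np.ndarray) -> dict[str, float]:
    """Planted size-model coefficients on the standardized scale: gamma *
    sd(covariate) / sd(log centroid size), from the realized sample."""
    sd_y = np.asarray(log_cs, float).std(ddof=1)
    out = {}
    for pred, gamma in truth.gamma_size.items():
        sd_x = truth.metadata[pred].to_numpy(float).std(ddof=1)
        out[pred] = float(gamma * sd_x / sd_y)
    return out
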