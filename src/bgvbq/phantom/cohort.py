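"""Between-subject sampling of tissue parameters for phantom cohorts.

Region values follow a single-factor Gaussian model per (circuit, parameter):

    value(j, r, p) = mu(r,p) + lam * sigma(r,p) * z_j(circuit(r), p)
                     + sqrt(1 - lam^2) * sigma(r,p) * eps_{j,r,p}

with ``z`` a latent standard-normal factor shared by every region of one
circuit and ``eps`` independent region noise, so the cross-region correlation
between two regions of the same circuit converges to lam_a * lam_b while
each region keeps its marginal (mu, sigma). Regions outside the three
circuits have lam = 0.

The default seed-subregion population parameters (mean, SD) are the MPM
cohort values: MT saturation in %, R1 and R2* in 1/s — limbic MT
1.1552 (0.1018), R1 0.866 (0.170), R2* 29.6 (0.75); associative 1.3050
(0.1128), 0.921 (0.177), 29.2 (0.63); motor 1.3026 (0.1150), 0.923 (0.178),
28.8 (0.6). Circuit-partner and cortical values are plausible grey/deep-grey
values chosen once for the phantom.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..core import PARAMETERS, ParameterMapSet
from .atlas import PhantomAtlas, SEED_ROLES

#: (region base name) -> {parameter: (population mean, population SD)}
DEFAULT_REGION_PARAMS: dict[str, dict[str, tuple[float, float]]] = {
    "stn_limbic": {"MT": (1.1552, 0.1018), "R1": (0.866, 0.170), "R2s": (29.6, 0.75)},
    "stn_associative": {"MT": (1.3050, 0.1128), "R1": (0.921, 0.177), "R2s": (29.2, 0.63)},
    "stn_motor": {"MT": (1.3026, 0.1150), "R1": (0.923, 0.178), "R2s": (28.8, 0.60)},
    "putamen_posterior": {"MT": (1.25, 0.10), "R1": (0.95, 0.15), "R2s": (30.0, 0.80)},
    "thalamus": {"MT": (1.40, 0.10), "R1": (1.00, 0.15), "R2s": (25.0, 0.80)},
    "pallidum_dorsal": {"MT": (1.50, 0.12), "R1": (1.05, 0.16), "R2s": (35.0, 1.00)},
    "caudate": {"MT": (1.00, 0.09), "R1": (0.75, 0.12), "R2s": (24.0, 0.80)},
    "putamen_anterior": {"MT": (1.20, 0.10), "R1": (0.90, 0.14), "R2s": (28.0, 0.80)},
    "pallidum_ventral": {"MT": (1.45, 0.12), "R1": (1.00, 0.15), "R2s": (33.0, 1.00)},
    "hippocampus": {"MT": (0.90, 0.08), "R1": (0.65, 0.07), "R2s": (18.0, 1.00)},
    "amygdala": {"MT": (0.90, 0.08), "R1": (0.65, 0.07), "R2s": (18.0, 1.00)},
    "m1": {"MT": (0.95, 0.08), "R1": (0.68, 0.07), "R2s": (19.0, 1.00)},
    "sma": {"MT": (0.95, 0.08), "R1": (0.68, 0.07), "R2s": (19.0, 1.00)},
    "superior_frontal": {"MT": (0.92, 0.08), "R1": (0.66, 0.07), "R2s": (18.5, 1.00)},
    "middle_frontal": {"MT": (0.92, 0.08), "R1": (0.66, 0.07), "R2s": (18.5, 1.00)},
    "acc": {"MT": (0.90, 0.08), "R1": (0.65, 0.07), "R2s": (18.0, 1.00)},
    "ofc": {"MT": (0.90, 0.08), "R1": (0.65, 0.07), "R2s": (18.0, 1.00)},
    "brain": {"MT": (1.00, 0.08), "R1": (0.70, 0.05), "R2s": (20.0, 1.50)},
}


def default_region_params() -> pd.DataFrame:
    rows = []
    for region, params in DEFAULT_REGION_PARAMS.items():
        for p, (mu, sd) in params.items():
            rows.append({"region": region, "parameter": p, "mean": mu, "sd": sd})
    return pd.DataFrame(rows)


def default_circuit_loadings(lam: float = 0.7) -> pd.DataFrame:
    rows = [{"circuit": c, "parameter": p, "loading": lam}
            for c in ("motor", "associative", "limbic") for p in PARAMETERS]
    return pd.DataFrame(rows)


class MissingRegionParameter(KeyError):
    def __init__(self, region: str, parameter: str):
        super().__init__(f"no population parameters for region {region!r}, "
                         f"parameter {parameter!r}")
        self.region, self.parameter = region, parameter


@dataclass
class CohortSpec:
    """Population parameters and noise model for one simulated cohort.

    ``voxel_sd_frac`` is the within-region voxel SD as a fraction of the
    region mean (spatial texture inside a region, on top of the subject's
    region value). ``age_range``/``sex_ratio`` mirror the 101-subject cohort
    (ages 40-71 years, 64/101 female); age and sex carry no effect on tissue
    values unless ``age_slope`` is set (units of the parameter per year,
    applied to every region).
    """

    n_subjects: int = 101
    region_params: pd.DataFrame = field(default_factory=default_region_params)
    circuit_loadings: pd.DataFrame = field(default_factory=default_circuit_loadings)
    age_range: tuple[float, float] = (40.0, 71.0)
    sex_ratio: float = 64 / 101
    voxel_sd_frac: float = 0.02
    a_app: float = 1000.0
    age_slope: dict[str, float] = field(default_factory=dict)
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if (self.region_params["sd"] < 0).any():
            raise ValueError("population SDs must be >= 0")
        lam = self.circuit_loadings["loading"]
        if ((lam < 0) | (lam > 1)).any():
            raise ValueError("circuit loadings must lie in [0, 1]")

    def lookup(self, region: str, parameter: str) -> tuple[float, float]:
        df = self.region_params
        row = df[(df["region"] == region) & (df["parameter"] == parameter)]
        if row.empty:
            raise MissingRegionParameter(region, parameter)
        return float(row["mean"].iloc[0]), float(row["sd"].iloc[0])

    def loading(self, circuit: str, parameter: str) -> float:
        if circuit in (None, "none"):
            return 0.0
        df = self.circuit_loadings
        row = df[(df["circuit"] == circuit) & (df["parameter"] == parameter)]
        return float(row["loading"].iloc[0]) if not row.empty else 0.0


def _base_name(region_name: str) -> str:
    return region_name[:-2] if region_name.endswith(("_l", "_r")) else region_name


@dataclass
class Cohort:
    """Sampled cohort: per-(subject, region, parameter) ground-truth values."""

    atlas: PhantomAtlas
    spec: CohortSpec
    region_values: pd.DataFrame  # long: subject, region, parameter, value
    covariates: pd.DataFrame  # subject_id, age, sex

    @property
    def n_subjects(self) -> int:
        return self.spec.n_subjects

    def values(self, region: str, parameter: str) -> np.ndarray:
        df = self.region_values
        sel = df[(df["region"] == region) & (df["parameter"] == parameter)]
        return sel.sort_values("subject")["value"].to_numpy()

    def render_maps(self, subject: int) -> ParameterMapSet:
        """Voxel maps for one subject: region values plus within-region noise.

        Deterministic per (spec.rng_seed, subject), independent of call order.
        """
        rng = np.random.default_rng([self.spec.rng_seed, 2654435761, subject])
        atlas, spec = self.atlas, self.spec
        shape = atlas.shape
        vols = {p: np.zeros(shape, dtype=np.float64) for p in PARAMETERS}
        df = self.region_values
        sub = df[df["subject"] == subject].set_index(["region", "parameter"])["value"]
        for _, row in atlas.regions.iterrows():
            region_mask = atlas.labels == row["label"]
            nvox = int(region_mask.sum())
            if nvox == 0:
                continue
            for p in PARAMETERS:
                mu, _sd = spec.lookup(_base_name(row["name"]), p)
                value = float(sub[(row["name"], p)])
                voxel_sd = spec.voxel_sd_frac * abs(mu)
                vols[p][region_mask] = value + rng.normal(0.0, voxel_sd, nvox)
        mask = atlas.brain_mask
        a_app = np.where(mask, spec.a_app, 0.0)
        return ParameterMapSet(mt=vols["MT"], r1=vols["R1"], r2s=vols["R2s"],
                               a_app=a_app, affine=atlas.affine, mask=mask)


def sample_cohort(atlas: PhantomAtlas, spec: CohortSpec) -> Cohort:
    """Draw per-subject region values and covariates from the factor model."""
    # fail fast if any atlas region lacks parameters
    for _, row in atlas.regions.iterrows():
        for p in PARAMETERS:
            spec.lookup(_base_name(row["name"]), p)

    rng = np.random.default_rng([spec.rng_seed, 1])
    n = spec.n_subjects
    circuits = ("motor", "associative", "limbic")
    z = {(c, p): rng.standard_normal(n) for c in circuits for p in PARAMETERS}

    ages = rng.uniform(*spec.age_range, n)
    sexes = (rng.uniform(size=n) < spec.sex_ratio).astype(int)
    age_c = ages - ages.mean()

    subj_col, region_col, param_col, value_col = [], [], [], []
    for _, region in atlas.regions.iterrows():
        name, circuit = region["name"], region["circuit"]
        for p in PARAMETERS:
            mu, sd = spec.lookup(_base_name(name), p)
            lam = spec.loading(circuit, p)
            eps = rng.standard_normal(n)
            shared = z[(circuit, p)] if circuit in circuits else 0.0
            vals = mu + lam * sd * shared + np.sqrt(1.0 - lam**2) * sd * eps
            vals = vals + spec.age_slope.get(p, 0.0) * age_c
            subj_col.append(np.arange(n))
            region_col.extend([name] * n)
            param_col.extend([p] * n)
            value_col.append(vals)
    rows = pd.DataFrame({
        "subject": np.concatenate(subj_col),
        "region": region_col,
        "parameter": param_col,
        "value": np.concatenate(value_col),
    })
    covariates = pd.DataFrame({
        "subject_id": [f"sub-{j:03d}" for j in range(n)],
        "age": ages,
        "sex": sexes,
    })
    return Cohort(atlas=atlas, spec=spec,
                  region_values=rows, covariates=covariates)


def sample_seed_value_table(means: dict[str, float], sds: dict[str, float],
                            corr: float, n: int,
                            rng: np.random.Generator) -> pd.DataFrame:
    """Draw per-subject seed-subregion values with a common pairwise correlation.

    Used by subregion-statistics studies where only the three extracted seed
    values matter (no spatial rendering); ``corr`` is the within-subject
    correlation between any two subregions.
    """
    names = list(means)
    k = len(names)
    cov = np.full((k, k), corr) + np.eye(k) * (1.0 - corr)
    sd = np.array([sds[nm] for nm in names])
    cov = cov * np.outer(sd, sd)
    mu = np.array([means[nm] for nm in names])
    draws = rng.multivariate_normal(mu, cov, size=n, method="cholesky")
    return pd.DataFrame(draws, columns=names)
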