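"""Synthetic serial-section series and cohort tables.

The generator emulates the study design the analysis assumes: two
retrogradely labeled forelimb motor pools (dorsally and ventrally
projecting) per animal, traced on ~30 serial coronal sections; a
cervical-enlargement diameter trend plus per-section rigid misalignment
distorting the raw traces; and per-animal cohort records — ladder-rung
crossing times and slips at 4/8/12 weeks (3-trial means), per-neuron
excitatory/inhibitory synapse counts, and perineuronal-net (PNN)
coverage categories.  Group presets ship pre-filled with the published
group means, SEMs and Ns, so simulated cohorts reproduce the reported
effect sizes; every series carries its ground truth for recovery tests.

Geometry convention: origin at the central canal, X medio-lateral
(lateral positive), Y dorso-ventral (dorsal positive), hemicord units
(baseline canal-to-lateral-edge distance 1).  The enlargement profile is
a mean-one Gaussian bump: a *relative* diameter modulation along the
anterior-posterior axis, so hemicord units remain comparable across
series regardless of the enlargement amplitude.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ParameterError
from .types import POOL_LABELS, SectionTrace, SeriesTrace

_TIMEPOINTS = (4, 8, 12)

# Base section geometry (hemicord units).  Five lateral-edge landmarks on
# the unit boundary arc, dorsal to ventral; four optical fiducials outside
# the grey matter, deliberately asymmetric so the rigid fit is always
# well-conditioned.
_EDGE_ANGLES_DEG = np.array([70.0, 35.0, 0.0, -35.0, -70.0])
_BASE_EDGE = np.column_stack(
    [np.cos(np.deg2rad(_EDGE_ANGLES_DEG)), np.sin(np.deg2rad(_EDGE_ANGLES_DEG))]
)
_BASE_OPTICAL_REFS = np.array(
    [[1.40, 1.20], [-1.20, 1.30], [-1.30, -1.20], [1.30, -1.35]]
)
_BASE_CANAL = np.zeros(2)
_BASE_AXIS = np.array([0.0, 1.0])


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimConfig:
    """Geometry-level simulation parameters (one series).

    Directional SDs and centers are in normalized hemicord units;
    ``rigid_jitter_rotation`` in radians.  ``enlargement_amplitude`` is
    the relative diameter increase at the series midpoint and
    ``enlargement_width`` its Gaussian width in sections.
    """

    seed: int = 0
    n_animals_per_group: int = 5
    n_sections: int = 30
    neurons_per_pool: int = 60
    pool_centers: dict = field(
        default_factory=lambda: {"dorsal": (0.50, -0.25), "ventral": (0.50, -0.55)}
    )
    sigmas: dict = field(
        default_factory=lambda: {"dorsal": (0.13, 0.13), "ventral": (0.11, 0.13)}
    )
    corr_mldv: float = 0.0
    enlargement_amplitude: float = 0.3
    enlargement_width: float = 5.0
    rigid_jitter_translation: float = 0.05
    rigid_jitter_rotation: float = 0.05
    landmark_noise: float = 0.005

    def __post_init__(self):
        for pool, (sml, sdv) in self.sigmas.items():
            if sml <= 0 or sdv <= 0:
                raise ParameterError(f"sigma for pool {pool!r} must be positive")
        if not abs(self.corr_mldv) < 1:
            raise ParameterError("corr_mldv must satisfy |corr| < 1")
        if self.n_sections < 5:
            raise ParameterError("n_sections must be >= 5")
        if self.enlargement_amplitude < 0:
            raise ParameterError("enlargement_amplitude must be >= 0")
        if self.enlargement_width <= 0:
            raise ParameterError("enlargement_width must be > 0")
        if self.landmark_noise < 0 or self.rigid_jitter_translation < 0:
            raise ParameterError("noise scales must be >= 0")


@dataclass(frozen=True)
class GroupPreset:
    """Published group-level parameters for one genotype x housing x age cell.

    Anatomy: ventral-pool directional SDs with their SEMs (dorsal-pool
    SDs derived from the published pool areas); behavior: ladder-rung
    crossing time and slips, mean and SEM per timepoint; synapse counts
    and PNN category probabilities with their group sizes.  SEMs are
    converted to between-animal SDs via SD = SEM * sqrt(N).
    """

    housing: str
    genotype: str
    age_weeks: int
    n_animals: int                  # anatomical group size (scatter N)
    sigma: dict                     # pool -> (sigma_ml, sigma_dv)
    sigma_sem: dict                 # pool -> (sem_ml, sem_dv)
    n_behavior: int
    crossing_mean: tuple            # per timepoint (4, 8, 12 wk), seconds
    crossing_sem: tuple
    slips_mean: tuple
    slips_sem: tuple
    n_synapse: int
    excitatory_mean: float
    excitatory_sem: float
    inhibitory_mean: float
    inhibitory_sem: float
    n_pnn: int
    pnn_probs: tuple                # (none, weak, strong), sums to 1

    @property
    def name(self) -> str:
        return f"{self.housing}/{self.genotype}/{self.age_weeks}wk"

    def __post_init__(self):
        if abs(sum(self.pnn_probs) - 1.0) > 1e-9:
            raise ParameterError("pnn_probs must sum to 1")
        if self.excitatory_mean < 0 or self.inhibitory_mean < 0:
            raise ParameterError("synapse-count means must be >= 0")
        if any(m < 0 for m in self.crossing_mean) or any(
            m < 0 for m in self.slips_mean
        ):
            raise ParameterError("behavior means must be >= 0")


def _sigma_from_si(si: float) -> float:
    """Isotropic directional SD consistent with an ellipse area si = pi*s^4."""
    return (si / math.pi) ** 0.25


def _sigma_ml_from_si(si: float, sigma_dv: float) -> float:
    """Back-solve sigma_ml from a published area and sigma_dv."""
    return math.sqrt(si / (math.pi * sigma_dv**2))


def _pnn(none, weak, strong):
    total = none + weak + strong
    return (none / total, weak / total, strong / total)


def _build_presets() -> dict:
    """Presets pre-filled with the published group means, SEMs and Ns."""
    # behavior trajectories per housing x genotype (crossing s, slips; 4/8/12 wk)
    behavior = {
        ("NH", "wt"): dict(
            n=14,
            crossing=((11.74, 9.48, 9.41), (0.86, 0.75, 0.67)),
            slips=((1.00, 1.10, 0.82), (0.22, 0.23, 0.14)),
        ),
        ("NH", "mut"): dict(
            n=12,
            crossing=((25.58, 18.92, 18.31), (2.56, 1.64, 1.89)),
            slips=((3.11, 2.61, 2.03), (0.66, 0.56, 0.37)),
        ),
        ("EE_birth", "wt"): dict(
            n=10,
            crossing=((10.37, 12.63, 11.00), (0.76, 0.90, 0.98)),
            slips=((1.00, 0.83, 0.47), (0.21, 0.16, 0.09)),
        ),
        ("EE_birth", "mut"): dict(
            n=9,
            crossing=((16.74, 15.85, 13.48), (1.71, 1.54, 1.19)),
            slips=((1.67, 1.07, 0.59), (0.49, 0.17, 0.15)),
        ),
        ("EE_4wk", "wt"): dict(
            n=19,
            crossing=((15.19, 12.61, 11.75), (1.17, 1.01, 0.62)),
            slips=((1.81, 1.00, 1.00), (0.24, 0.15, 0.24)),
        ),
        ("EE_4wk", "mut"): dict(
            n=11,
            crossing=((34.06, 23.91, 21.55), (2.09, 2.17, 2.22)),
            slips=((5.30, 2.24, 2.394), (0.59, 0.32, 0.3140)),
        ),
    }
    # synapse counts at 12 wk, N = 3 per group
    synapse = {
        ("NH", "wt"): (8.32, 0.90, 133.5, 10.52),
        ("NH", "mut"): (8.13, 0.67, 127.3, 28.76),
        ("EE_birth", "wt"): (15.99, 2.51, 122.5, 3.85),
        ("EE_birth", "mut"): (16.81, 3.88, 125.0, 6.63),
        ("EE_4wk", "wt"): (8.70, 0.93, 119.4, 12.0),
        ("EE_4wk", "mut"): (8.43, 0.24, 113.2, 2.15),
    }
    # PNN category percentages at 4 wk (none, weak, strong), N = 3
    pnn = {
        ("NH", "wt"): _pnn(63.6, 30.7, 5.7),
        ("NH", "mut"): _pnn(70.4, 27.2, 2.4),
        ("EE_birth", "wt"): _pnn(66.6, 29.0, 4.4),
        ("EE_birth", "mut"): _pnn(71.6, 25.9, 2.6),
    }
    pnn[("EE_4wk", "wt")] = pnn[("NH", "wt")]
    pnn[("EE_4wk", "mut")] = pnn[("NH", "mut")]

    # anatomy: (n, ventral (sml, sdv, sem_ml, sem_dv), ventral SI (v, sem),
    #           dorsal SI (v, sem)); a None sigma_ml is back-solved from SI
    anatomy_12 = {
        ("NH", "wt"): (7, (0.11, 0.13, 0.0061, 0.0076), (0.00069, 0.00012), (0.00089, 0.00015)),
        ("NH", "mut"): (5, (0.12, 0.18, 0.0080, 0.0114), (0.00124, 0.00015), (0.00102, 0.00027)),
        ("EE_birth", "wt"): (5, (0.1149, 0.1372, 0.0068, 0.0108), (0.00084, 0.00024), (0.00102, 0.00021)),
        ("EE_birth", "mut"): (3, (0.0979, 0.1506, 0.0074, 0.0104), (0.00065, 0.00007), (0.00113, 0.00050)),
        ("EE_4wk", "wt"): (8, (0.1068, 0.1157, 0.0021, 0.0031), (0.00045, 0.00004), (0.00065, 0.00006)),
        ("EE_4wk", "mut"): (3, (0.1121, 0.1642, 0.004982, 0.0375), (0.00113, 0.00041), (0.00066, 0.00015)),
    }
    anatomy_4 = {
        ("NH", "wt"): (5, (None, 0.1587, None, 0.0139), (0.00124, 0.00020), (0.00141, 0.00030)),
        ("NH", "mut"): (5, (None, 0.2486, None, 0.0204), (0.00371, 0.00071), (0.00132, 0.00021)),
        ("EE_birth", "wt"): (5, (None, 0.1564, None, 0.0109), (0.00130, 0.00023), (0.00106, 0.00023)),
        ("EE_birth", "mut"): (5, (None, 0.1923, None, 0.0154), (0.00212, 0.00049), (0.00151, 0.00032)),
    }
    # enrichment starting at 4 wk is indistinguishable from NH at 4 wk of age
    anatomy_4[("EE_4wk", "wt")] = anatomy_4[("NH", "wt")]
    anatomy_4[("EE_4wk", "mut")] = anatomy_4[("NH", "mut")]

    presets = {}
    for age, anatomy in ((12, anatomy_12), (4, anatomy_4)):
        for (housing, genotype), (n, vent, si_v, si_d) in anatomy.items():
            sml, sdv, sem_ml, sem_dv = vent
            if sml is None:
                sml = _sigma_ml_from_si(si_v[0], sdv)
                sem_ml = sml * (si_v[1] / si_v[0]) / 2.0
            sd_iso = _sigma_from_si(si_d[0])
            sem_d = sd_iso * (si_d[1] / si_d[0]) / 4.0
            beh = behavior[(housing, genotype)]
            exc_m, exc_s, inh_m, inh_s = synapse[(housing, genotype)]
            key = (housing, genotype, age)
            presets[key] = GroupPreset(
                housing=housing,
                genotype=genotype,
                age_weeks=age,
                n_animals=n,
                sigma={"ventral": (sml, sdv), "dorsal": (sd_iso, sd_iso)},
                sigma_sem={"ventral": (sem_ml, sem_dv), "dorsal": (sem_d, sem_d)},
                n_behavior=beh["n"],
                crossing_mean=beh["crossing"][0],
                crossing_sem=beh["crossing"][1],
                slips_mean=beh["slips"][0],
                slips_sem=beh["slips"][1],
                n_synapse=3,
                excitatory_mean=exc_m,
                excitatory_sem=exc_s,
                inhibitory_mean=inh_m,
                inhibitory_sem=inh_s,
                n_pnn=3,
                pnn_probs=pnn[(housing, genotype)],
            )
    return presets


PRESETS: dict = _build_presets()


def get_preset(name: str, **overrides) -> GroupPreset:
    """Look up a preset by ``housing/genotype/age`` (e.g. ``NH/mut/12wk``)."""
    parts = name.split("/")
    if len(parts) != 3:
        raise ParameterError(f"preset name must be housing/genotype/AGEwk, got {name!r}")
    housing, genotype, age = parts
    key = (housing, genotype, int(age.rstrip("wk")))
    if key not in PRESETS:
        raise ParameterError(f"unknown preset {name!r}")
    p = PRESETS[key]
    return replace(p, **overrides) if overrides else p


# ---------------------------------------------------------------------------
# geometry generators
# ---------------------------------------------------------------------------

def enlargement_profile(n_sections: int, amplitude: float, width: float) -> np.ndarray:
    """Mean-one Gaussian diameter modulation along the section index.

    The bump peaks at the series midpoint with relative height
    ``amplitude``; dividing by the profile mean keeps the series-average
    diameter at the hemicord unit, so mid/end ratio ~ 1 + amplitude while
    coordinates stay on a common scale.
    """
    i = np.arange(n_sections, dtype=float)
    mid = (n_sections - 1) / 2.0
    f = 1.0 + amplitude * np.exp(-((i - mid) ** 2) / (2.0 * width**2))
    return f / f.mean()


def gen_pool(n, center, sigma_ml, sigma_dv, corr=0.0, seed=None, rng=None):
    """Draw ``n`` points from a bivariate normal with the stated moments."""
    if n < 1:
        raise ParameterError("n must be >= 1")
    if sigma_ml <= 0 or sigma_dv <= 0:
        raise ParameterError("sigma_ml and sigma_dv must be positive")
    if not abs(corr) < 1:
        raise ParameterError("|corr| must be < 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    cov = np.array(
        [
            [sigma_ml**2, corr * sigma_ml * sigma_dv],
            [corr * sigma_ml * sigma_dv, sigma_dv**2],
        ]
    )
    L = np.linalg.cholesky(cov)
    z = rng.standard_normal((n, 2))
    return np.asarray(center, float) + z @ L.T


def _rotation(theta: float) -> np.ndarray:
    c, s = math.cos(theta), math.sin(theta)
    return np.array([[c, -s], [s, c]])


def gen_series(
    config: SimConfig,
    group: GroupPreset | None = None,
    animal_seed: int | None = None,
    animal_id: str = "sim",
    sigma_override: dict | None = None,
) -> SeriesTrace:
    """Generate one animal's serial-section trace with known ground truth.

    Each pool's neurons are drawn as a single 2-D cloud (the ground
    truth), distributed uniformly over sections, then distorted: tissue
    (neurons and lateral-edge landmarks) is scaled about the canal by the
    enlargement profile at the section, landmark noise added, and finally
    a per-section rigid jitter applied to everything including the four
    optical fiducials.  Ground truth and all distortion parameters are
    kept in ``series.meta`` for recovery tests.
    """
    seed = config.seed if animal_seed is None else animal_seed
    rng = np.random.default_rng(seed)
    sigmas = dict(config.sigmas)
    if group is not None:
        sigmas.update(group.sigma)
    if sigma_override:
        sigmas.update(sigma_override)

    truth, labels_all, pts_all, section_of = {}, [], [], []
    for pool in POOL_LABELS:
        sml, sdv = sigmas[pool]
        pts = gen_pool(
            config.neurons_per_pool,
            config.pool_centers[pool],
            sml,
            sdv,
            config.corr_mldv,
            rng=rng,
        )
        truth[pool] = pts
        pts_all.append(pts)
        labels_all.extend([pool] * len(pts))
        section_of.append(rng.integers(0, config.n_sections, size=len(pts)))
    pts_all = np.vstack(pts_all)
    labels_all = np.asarray(labels_all, dtype=object)
    section_of = np.concatenate(section_of)

    profile = enlargement_profile(
        config.n_sections, config.enlargement_amplitude, config.enlargement_width
    )
    sections = []
    for i in range(config.n_sections):
        in_sec = section_of == i
        f = profile[i]
        neurons = pts_all[in_sec] * f  # canal at origin: scaling about canal
        edge = _BASE_EDGE * f
        refs = _BASE_OPTICAL_REFS.copy()
        if config.landmark_noise > 0:
            edge = edge + rng.normal(0.0, config.landmark_noise, edge.shape)
            refs = refs + rng.normal(0.0, config.landmark_noise, refs.shape)
        theta = (
            rng.normal(0.0, config.rigid_jitter_rotation)
            if config.rigid_jitter_rotation > 0
            else 0.0
        )
        shift = (
            rng.normal(0.0, config.rigid_jitter_translation, 2)
            if config.rigid_jitter_translation > 0
            else np.zeros(2)
        )
        R = _rotation(theta)
        sections.append(
            SectionTrace(
                section_index=i,
                z_um=40.0 * i,
                neurons=neurons @ R.T + shift if len(neurons) else neurons,
                neuron_pools=labels_all[in_sec],
                lateral_edge=edge @ R.T + shift,
                central_canal=R @ _BASE_CANAL + shift,
                midsagittal_axis=R @ _BASE_AXIS,
                optical_refs=refs @ R.T + shift,
            )
        )
    meta = {
        "ground_truth": truth,
        "true_sigma": sigmas,
        "enlargement_profile": profile,
        "seed": seed,
    }
    return SeriesTrace(
        animal_id=animal_id,
        genotype=group.genotype if group else "wt",
        housing=group.housing if group else "NH",
        age_weeks=group.age_weeks if group else 12,
        sections=sections,
        provenance=f"synthetic (seed={seed})",
        meta=meta,
    )


# ---------------------------------------------------------------------------
# cohort generator
# ---------------------------------------------------------------------------

@dataclass
class CohortTables:
    """Per-animal cohort tables feeding the statistics layer."""

    behavior: pd.DataFrame   # animal_id, genotype, housing, timepoint_weeks, crossing_time_s, slips
    scatter: pd.DataFrame    # animal_id, genotype, housing, age_weeks, pool, n_neurons, sd_ml, sd_dv, si
    synapse: pd.DataFrame    # animal_id, genotype, housing, neuron_id, excitatory_count, inhibitory_count
    pnn: pd.DataFrame        # animal_id, genotype, housing, neuron_id, category
    truth: pd.DataFrame      # animal_id, pool, true_sigma_ml, true_sigma_dv, true_si

    def write(self, directory):
        from pathlib import Path

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name in ("behavior", "scatter", "synapse", "pnn", "truth"):
            getattr(self, name).to_csv(directory / f"{name}.csv", index=False)

    @classmethod
    def read(cls, directory):
        from pathlib import Path

        directory = Path(directory)
        return cls(
            **{
                name: pd.read_csv(directory / f"{name}.csv")
                for name in ("behavior", "scatter", "synapse", "pnn", "truth")
            }
        )


# between-animal correlation of ladder-rung performance across timepoints
_BEHAVIOR_ICC = 0.6
# fraction of the marginal behavior SD attributed to trial-to-trial noise
_TRIAL_SD_FRACTION = 0.3
_N_TRIALS = 3
_SYNAPSE_NEURONS_PER_ANIMAL = 20
_PNN_NEURONS_PER_ANIMAL = 60


def _animal_sigma(rng, preset):
    """Per-animal true directional SDs around the group means."""
    out = {}
    for pool in POOL_LABELS:
        mean = preset.sigma[pool]
        sem = preset.sigma_sem[pool]
        n = preset.n_animals
        sds = [s * math.sqrt(n) for s in sem]
        out[pool] = tuple(
            max(0.02, rng.normal(m, sd)) for m, sd in zip(mean, sds)
        )
    return out


def _behavior_rows(rng, preset, animal_id, n_trials=_N_TRIALS):
    u = rng.standard_normal()
    rows = []
    for tp, mean, sem in zip(_TIMEPOINTS, preset.crossing_mean, preset.crossing_sem):
        rows.append((tp, "crossing_time_s", _behavior_value(rng, mean, sem, preset.n_behavior, u, n_trials)))
    for tp, mean, sem in zip(_TIMEPOINTS, preset.slips_mean, preset.slips_sem):
        rows.append((tp, "slips", max(0.0, _behavior_value(rng, mean, sem, preset.n_behavior, u, n_trials))))
    wide = {}
    for tp, kind, val in rows:
        wide.setdefault(tp, {})[kind] = val
    return [
        dict(
            animal_id=animal_id,
            genotype=preset.genotype,
            housing=preset.housing,
            timepoint_weeks=tp,
            crossing_time_s=vals["crossing_time_s"],
            slips=vals["slips"],
        )
        for tp, vals in sorted(wide.items())
    ]


def _behavior_value(rng, mean, sem, n, u, n_trials):
    """3-trial mean with marginal SD = sem * sqrt(n) across animals."""
    sd_total = sem * math.sqrt(n)
    if sd_total == 0:
        return mean
    trial_sd = _TRIAL_SD_FRACTION * sd_total
    sd_b = math.sqrt(max(sd_total**2 - trial_sd**2 / n_trials, 0.0))
    rho = math.sqrt(_BEHAVIOR_ICC)
    latent = mean + sd_b * (rho * u + math.sqrt(1 - rho**2) * rng.standard_normal())
    trials = latent + trial_sd * rng.standard_normal(n_trials)
    return float(trials.mean())


def gen_cohort(
    presets,
    seed: int,
    config: SimConfig | None = None,
    include_series: bool = True,
):
    """Generate one full cohort: series + behavior/synapse/PNN/scatter tables.

    The scatter table holds the *measured* per-animal scatter statistics
    computed from each animal's ground-truth pooled cloud (identical to
    the pipeline output for an undistorted series); the truth table holds
    the per-animal generating parameters.  With ``include_series=False``
    only the tables are produced (fast path for statistical simulations).
    """
    from .morphometry import scatter_index

    if isinstance(presets, GroupPreset):
        presets = [presets]
    if not presets:
        raise ParameterError("need at least one preset")
    rng = np.random.default_rng(seed)
    base_config = config or SimConfig(seed=seed)

    behavior, scatter, synapse, pnn, truth, series_list = [], [], [], [], [], []
    for preset in presets:
        for k in range(preset.n_animals):
            animal_id = f"{preset.housing}_{preset.genotype}_{preset.age_weeks}wk_a{k}"
            sigmas = _animal_sigma(rng, preset)
            animal_seed = int(rng.integers(0, 2**31 - 1))
            if include_series:
                s = gen_series(
                    base_config,
                    group=preset,
                    animal_seed=animal_seed,
                    animal_id=animal_id,
                    sigma_override=sigmas,
                )
                series_list.append(s)
                clouds = s.meta["ground_truth"]
            else:
                crng = np.random.default_rng(animal_seed)
                clouds = {
                    pool: gen_pool(
                        base_config.neurons_per_pool,
                        base_config.pool_centers[pool],
                        *sigmas[pool],
                        base_config.corr_mldv,
                        rng=crng,
                    )
                    for pool in POOL_LABELS
                }
            for pool in POOL_LABELS:
                res = scatter_index(clouds[pool])
                scatter.append(
                    dict(
                        animal_id=animal_id,
                        genotype=preset.genotype,
                        housing=preset.housing,
                        age_weeks=preset.age_weeks,
                        pool=pool,
                        n_neurons=res.n_neurons,
                        sd_ml=res.sd_ml,
                        sd_dv=res.sd_dv,
                        si=res.si,
                    )
                )
                sml, sdv = sigmas[pool]
                truth.append(
                    dict(
                        animal_id=animal_id,
                        pool=pool,
                        true_sigma_ml=sml,
                        true_sigma_dv=sdv,
                        true_si=math.pi * sml**2 * sdv**2,
                    )
                )
            behavior.extend(_behavior_rows(rng, preset, animal_id))
            exc_true = max(0.2, rng.normal(preset.excitatory_mean, preset.excitatory_sem * math.sqrt(preset.n_synapse)))
            inh_true = max(0.2, rng.normal(preset.inhibitory_mean, preset.inhibitory_sem * math.sqrt(preset.n_synapse)))
            for j in range(_SYNAPSE_NEURONS_PER_ANIMAL):
                synapse.append(
                    dict(
                        animal_id=animal_id,
                        genotype=preset.genotype,
                        housing=preset.housing,
                        neuron_id=j,
                        excitatory_count=int(rng.poisson(exc_true)),
                        inhibitory_count=int(rng.poisson(inh_true)),
                    )
                )
            cats = rng.multinomial(_PNN_NEURONS_PER_ANIMAL, preset.pnn_probs)
            j = 0
            for cat, count in zip(("none", "weak", "strong"), cats):
                for _ in range(count):
                    pnn.append(
                        dict(
                            animal_id=animal_id,
                            genotype=preset.genotype,
                            housing=preset.housing,
                            neuron_id=j,
                            category=cat,
                        )
                    )
                    j += 1

    tables = CohortTables(
        behavior=pd.DataFrame(behavior),
        scatter=pd.DataFrame(scatter),
        synapse=pd.DataFrame(synapse),
        pnn=pd.DataFrame(pnn),
        truth=pd.DataFrame(truth),
    )
    return (tables, series_list) if include_series else (tables, [])


def gen_behavior_link(si_values, slope, intercept, noise_sd, seed=None):
    """Linear link value_i = intercept + slope * si_i + N(0, noise_sd)."""
    if noise_sd < 0:
        raise ParameterError("noise_sd must be >= 0")
    si = np.asarray(si_values, float)
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, noise_sd, si.shape) if noise_sd > 0 else 0.0
    return intercept + slope * si + noise
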