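"""Synthetic task-fMRI cohorts with the statistical structure the analysis assumes.

The generator emulates, at the contrast/trial-map level (no time series, no
GLM), the features that make brain-trait prediction hard and brain-state
decoding easy:

* **person-wise global offsets** — every subject carries additive offsets
  shared across voxels (and person x region offsets shared within regions).
  Components common to both task conditions cancel in a condition contrast
  but dominate implicit-baseline maps; *condition-differential* components
  survive the contrast and produce the high between-network correlations of
  contrast maps seen in real data, which image-wise centering removes
  (global) or dampens (regional);
* **a strong within-person state signal** — each trial map contains
  ``beta_state * a_it * w_state`` where the latent affect ``a_it`` also
  drives the trial's 1-5 Likert rating, so patterns can track momentary
  affect at high within-person correlations;
* **a weak, spatially distributed trait signal** — a sparse-then-smoothed
  region-level weight map ``w_trait`` (random sign per region, constant
  within region, confined to a configurable subset of networks) scaled by
  ``beta_trait`` and the subject's latent stress-vulnerability;
* **a questionnaire hierarchy with imperfect reliability** — six neuroticism
  facets loading on a shared domain factor, convergent/discriminant traits,
  and observed scores attenuated by a reliability coefficient.

The brain couples to the *facet-specific* component of vulnerability to
stress (the part orthogonal to the shared neuroticism domain), so the broad
domain score is unpredictable from brain data while the facet is not.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .images import BrainMaps
from .parcellation import Atlas
from .theory_models import SignatureMap

__all__ = [
    "SimConfig",
    "CohortData",
    "FACETS",
    "SIGNATURE_KINDS",
    "generate_atlas",
    "generate_cohort",
    "generate_signature",
    "build_contrast",
]

FACETS = (
    "anxiety",
    "depression",
    "vulnerability",
    "anger",
    "impulsiveness",
    "self_consciousness",
)

SIGNATURE_KINDS = ("negative-affect", "fear", "sadness", "anger", "fear2")

NETWORK_NAMES = (
    "visual",
    "somatomotor",
    "dorsal_attention",
    "ventral_attention",
    "limbic",
    "frontoparietal",
    "default_mode",
)

THEORY_REGION_NAMES = (
    "amygdala_left",
    "amygdala_right",
    "anterior_insula_left",
    "anterior_insula_right",
    "dacc_left",
    "dacc_right",
)

#: slope of the affine map from latent affect to the 1-5 rating scale
RATING_SCALE = 0.8


def _default_facet_structure() -> dict[str, float]:
    return {f: 0.6 for f in FACETS}


@dataclass
class SimConfig:
    """Configuration of one synthetic cohort.

    All signal units are arbitrary contrast units; SDs are in those units.
    The defaults are the package's documented study conditions: a 12x12x12
    grid (1,728 voxels), 40 contiguous regions in 7 networks, 200 subjects
    and 20 trials per condition, calibrated so that contrast maps show mean
    between-network correlations near .7, trial maps decode ratings
    within-person at r >= .85, and the trait-carrying facet reaches
    cross-validated between-person correlations near .2.
    """

    n_subjects: int = 200
    n_trials_neg: int = 20
    n_trials_neu: int = 20
    grid_shape: tuple[int, int, int] = (12, 12, 12)
    n_regions: int = 40
    n_networks: int = 7
    # person-level variance components (see module docstring)
    sigma_global: float = 1.0  # condition-common global offset g_i
    sigma_global_diff: float = 0.02  # condition-differential global offset
    sigma_region: float = 1.0  # condition-common person x region offsets
    sigma_region_diff: float = 0.16  # condition-differential person x region
    sigma_noise: float = 1.0  # voxel x trial noise
    # trait signal
    beta_trait: float = 0.025
    trait_support: float = 0.5  # fraction of voxels carrying trait signal
    trait_networks: tuple[int, ...] | None = None  # default: networks 1,2,5,6
    beta_trait_faces_ratio: float = 0.25  # trait signal attenuation, faces task
    # state signal and ratings
    beta_state: float = 0.2
    sigma_reactivity: float = 0.25  # SD of per-person affect reactivity
    sigma_state: float = 0.6  # SD of trial-level affect fluctuations
    rating_noise: float = 0.3  # SD of self-report noise (pre-rounding)
    # questionnaire model
    facet_structure: dict[str, float] = field(default_factory=_default_facet_structure)
    reliability: float | dict[str, float] = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(s) for s in self.grid_shape)
        if self.trait_networks is None:
            # somatomotor, dorsal attention, frontoparietal, default mode under
            # the canonical 7-network naming; clipped for smaller partitions
            preferred = [k for k in (1, 2, 5, 6) if k < self.n_networks]
            self.trait_networks = tuple(preferred) or (0,)
        self.trait_networks = tuple(int(k) for k in self.trait_networks)
        sds = (
            self.sigma_global,
            self.sigma_global_diff,
            self.sigma_region,
            self.sigma_region_diff,
            self.sigma_noise,
            self.sigma_reactivity,
            self.sigma_state,
            self.rating_noise,
        )
        if any(s < 0 for s in sds):
            raise ValueError("all SDs must be >= 0")
        if not 0 < self.trait_support <= 1:
            raise ValueError("trait_support must lie in (0, 1]")
        rels = (
            self.reliability.values()
            if isinstance(self.reliability, dict)
            else [self.reliability]
        )
        if any(not 0 < r <= 1 for r in rels):
            raise ValueError("reliability must lie in (0, 1]")
        n_vox = int(np.prod(self.grid_shape))
        if not n_vox >= self.n_regions >= self.n_networks >= 1:
            raise ValueError("need voxel count >= n_regions >= n_networks >= 1")
        if any(not 0 <= k < self.n_networks for k in self.trait_networks):
            raise ValueError("trait_networks outside the network range")

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.grid_shape))

    def reliability_of(self, trait: str) -> float:
        if isinstance(self.reliability, dict):
            return self.reliability.get(trait, 0.8)
        return self.reliability

    # -- YAML round trip ---------------------------------------------------
    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    # independent, reproducible stream per generator component
    return np.random.default_rng([int(config.seed), int(stream)])


def _snake_order(shape: tuple[int, int, int]) -> np.ndarray:
    """Flat C-order voxel indices in boustrophedon (snake) traversal.

    Consecutive entries are 6-neighbours on the grid, so any run of
    consecutive entries is a spatially contiguous parcel.
    """
    nx, ny, nz = shape
    order = []
    for x in range(nx):
        ys = range(ny) if x % 2 == 0 else range(ny - 1, -1, -1)
        for j, y in enumerate(ys):
            forward = (x * ny + j) % 2 == 0
            zs = range(nz) if forward else range(nz - 1, -1, -1)
            for z in zs:
                order.append((x * ny + y) * nz + z)
    return np.asarray(order, dtype=int)


def generate_atlas(config: SimConfig) -> Atlas:
    """Partition the voxel grid into contiguous regions grouped into networks.

    Regions are near-equal runs along a snake traversal of the grid (hence
    spatially contiguous); region r belongs to network r mod n_networks, so
    every network is spatially distributed across the volume. The first six
    regions carry the canonical theory-ROI names (bilateral amygdala,
    anterior insula, dACC) so the theory-driven battery runs verbatim.
    """
    n_vox = config.n_voxels
    if config.n_regions > n_vox:
        raise ValueError("more regions than voxels: impossible partition")
    order = _snake_order(config.grid_shape)
    region_of_voxel = np.empty(n_vox, dtype=int)
    for rid, chunk in enumerate(np.array_split(order, config.n_regions)):
        region_of_voxel[chunk] = rid
    network_of_region = np.arange(config.n_regions) % config.n_networks
    region_names = [f"region_{i:03d}" for i in range(config.n_regions)]
    for i, name in enumerate(THEORY_REGION_NAMES[: min(6, config.n_regions)]):
        region_names[i] = name
    network_names = list(NETWORK_NAMES[: config.n_networks])
    network_names += [
        f"network_{i}" for i in range(len(network_names), config.n_networks)
    ]
    return Atlas(
        region_of_voxel=region_of_voxel,
        network_of_region=network_of_region,
        region_names=region_names,
        network_names=network_names,
    )


def _grid_coords(shape) -> np.ndarray:
    return np.indices(shape).reshape(3, -1).T


def _observed(latent: np.ndarray, rel: float, rng: np.random.Generator) -> np.ndarray:
    """Attenuate a unit-variance latent by reliability and move to T-scores."""
    score = math.sqrt(rel) * latent + math.sqrt(1.0 - rel) * rng.standard_normal(latent.size)
    return 50.0 + 10.0 * score


@dataclass
class CohortData:
    """One synthetic cohort: maps, ratings, traits and ground truth."""

    config: SimConfig
    atlas: Atlas
    trial_maps: BrainMaps  # scenes task, subject-trials x voxels
    ratings: np.ndarray  # per trial, 1-5 Likert
    contrast_maps: BrainMaps  # scenes task, control baseline
    maps: dict[tuple[str, str], BrainMaps]  # (task, baseline) -> subjects x voxels
    traits: pd.DataFrame
    truth: dict

    def maps_for(self, task: str = "scenes", baseline: str = "control") -> BrainMaps:
        try:
            return self.maps[(task, baseline)]
        except KeyError:
            raise KeyError(f"no maps for task={task!r}, baseline={baseline!r}") from None

    @property
    def subjects(self) -> np.ndarray:
        return self.traits["subject"].to_numpy()

    def save(self, outdir) -> None:
        """Write maps (NIfTI), traits/ratings (CSV), truth (npz), config (YAML)."""
        from .images import save_maps_nifti

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.config.to_yaml(outdir / "sim_config.yaml")
        self.traits.to_csv(outdir / "traits.csv", index=False)
        self.trial_maps.obs_meta.to_csv(outdir / "trials.csv", index=False)
        save_maps_nifti(self.trial_maps, outdir / "trial_maps_scenes.nii.gz")
        for (task, baseline), maps in self.maps.items():
            save_maps_nifti(maps, outdir / f"contrast_{task}_{baseline}.nii.gz")
        self.atlas.save(self.contrast_maps, outdir / "atlas.nii.gz", outdir / "atlas.json")
        np.savez_compressed(
            outdir / "truth.npz",
            **{k: v for k, v in self.truth.items() if isinstance(v, np.ndarray)},
        )


def build_contrast(trial_maps: BrainMaps, trial_mask=None) -> BrainMaps:
    """Per-subject condition contrast: mean(negative) - mean(neutral) trials.

    ``trial_mask`` optionally restricts which trials enter (e.g. odd/even
    halves for split-half reliability). Subjects are ordered as they first
    appear in the trial metadata.
    """
    meta = trial_maps.obs_meta
    if meta is None or "subject" not in meta or "condition" not in meta:
        raise ValueError("trial maps need subject and condition metadata")
    use = np.ones(trial_maps.n_obs, bool) if trial_mask is None else np.asarray(trial_mask, bool)
    subjects = meta["subject"].unique()
    rows = np.empty((subjects.size, trial_maps.n_voxels))
    subj = meta["subject"].to_numpy()
    cond = meta["condition"].to_numpy()
    for i, s in enumerate(subjects):
        neg = use & (subj == s) & (cond == "negative")
        neu = use & (subj == s) & (cond == "neutral")
        if not neg.any() or not neu.any():
            raise ValueError(f"subject {s!r} lacks trials in one condition")
        rows[i] = trial_maps.data[neg].mean(axis=0) - trial_maps.data[neu].mean(axis=0)
    return BrainMaps(
        data=rows,
        voxel_coords=trial_maps.voxel_coords,
        grid_shape=trial_maps.grid_shape,
        obs_meta=pd.DataFrame({"subject": subjects}),
        provenance=list(trial_maps.provenance) + ["contrast:neg-neu"],
    )


def _trait_weights(config: SimConfig, atlas: Atlas, rng: np.random.Generator) -> np.ndarray:
    """Sparse-then-smoothed trait weight map: per-region random sign,
    constant within region, confined to the configured networks."""
    candidates = [
        r
        for r in range(atlas.n_regions)
        if atlas.network_of_region[r] in config.trait_networks
    ]
    if not candidates:
        raise ValueError("trait_networks contain no regions")
    rng.shuffle(candidates)
    sizes = atlas.region_sizes()
    target = config.trait_support * config.n_voxels
    chosen, covered = [], 0
    for r in candidates:
        if covered >= target and chosen:
            break
        chosen.append(r)
        covered += sizes[r]
    w = np.zeros(config.n_voxels)
    signs = rng.choice([-1.0, 1.0], size=len(chosen))
    for s, r in zip(signs, chosen):
        w[atlas.region_of_voxel == r] = s
    return w


def generate_cohort(config: SimConfig) -> CohortData:
    """Simulate one cohort of trial maps, contrast maps, ratings and traits.

    Trial model (scenes task), with s_c = +1 for negative and -1 for neutral
    trials:

        X_itv = g_i + h_ir + s_c * (d_i + m_ir + beta_trait * z_i * w_trait_v) / 2
                + beta_state * a_it * w_state_v + e_itv

    so that the condition contrast equals
    d_i + m_ir + beta_trait * z_i * w_trait_v + beta_state * (a_neg - a_neu)_i
    * w_state_v + averaged noise, while implicit-baseline maps additionally
    retain g_i and h_ir. The latent affect a_it = (1 + rho_i) * s_c + s_it
    drives the Likert rating through an affine map with pre-rounding noise.
    Faces-task maps follow the same person-level model with an independent
    state pattern and an attenuated trait signal, generated directly at the
    contrast level.
    """
    atlas = generate_atlas(config)
    V, n, R = config.n_voxels, config.n_subjects, config.n_regions
    reg = atlas.region_of_voxel

    rng_w = _rng(config, 1)
    w_state = rng_w.normal(1.0, 0.5, size=R)[reg]
    w_state_faces = rng_w.normal(1.0, 0.5, size=R)[reg]
    w_trait = _trait_weights(config, atlas, rng_w)

    rng_s = _rng(config, 2)
    g = rng_s.normal(0.0, config.sigma_global, n)
    d_scenes = rng_s.normal(0.0, config.sigma_global_diff, n)
    d_faces = rng_s.normal(0.0, config.sigma_global_diff, n)
    h = rng_s.normal(0.0, config.sigma_region, (n, R))
    m_scenes = rng_s.normal(0.0, config.sigma_region_diff, (n, R))
    m_faces = rng_s.normal(0.0, config.sigma_region_diff, (n, R))
    reactivity = rng_s.normal(0.0, config.sigma_reactivity, n)

    # questionnaire latents: shared domain + facet-specific components
    rng_t = _rng(config, 3)
    domain = rng_t.standard_normal(n)
    uniques = {f: rng_t.standard_normal(n) for f in FACETS}
    lam = {f: float(config.facet_structure.get(f, 0.6)) for f in FACETS}
    facet_latents = {
        f: lam[f] * domain + math.sqrt(1.0 - lam[f] ** 2) * uniques[f] for f in FACETS
    }
    z = uniques["vulnerability"]  # brain couples to the facet-specific part

    # scenes trials ---------------------------------------------------------
    rng_x = _rng(config, 4)
    n_trials = config.n_trials_neg + config.n_trials_neu
    s_c = np.concatenate(
        [np.ones(config.n_trials_neg), -np.ones(config.n_trials_neu)]
    )  # per-trial condition sign, same layout per subject
    a = (1.0 + reactivity)[:, None] * s_c[None, :] + rng_x.normal(
        0.0, config.sigma_state, (n, n_trials)
    )
    rating_raw = 3.0 + RATING_SCALE * a + rng_x.normal(0.0, config.rating_noise, a.shape)
    ratings = np.clip(np.rint(rating_raw), 1, 5).astype(int)

    person_common = g[:, None] + h[:, reg]  # (n, V)
    person_diff = (
        d_scenes[:, None]
        + m_scenes[:, reg]
        + config.beta_trait * z[:, None] * w_trait[None, :]
    )
    noise = rng_x.normal(0.0, config.sigma_noise, (n, n_trials, V))
    X = (
        person_common[:, None, :]
        + 0.5 * s_c[None, :, None] * person_diff[:, None, :]
        + config.beta_state * a[:, :, None] * w_state[None, None, :]
        + noise
    ).reshape(n * n_trials, V)
    del noise

    coords = _grid_coords(config.grid_shape)
    subj_ids = np.array([f"sub-{i:03d}" for i in range(n)])
    trial_meta = pd.DataFrame(
        {
            "subject": np.repeat(subj_ids, n_trials),
            "condition": np.tile(
                np.where(s_c > 0, "negative", "neutral"), n
            ),
            "trial": np.tile(np.arange(n_trials), n),
            "rating": ratings.ravel(),
        }
    )
    trial_maps = BrainMaps(
        data=X,
        voxel_coords=coords,
        grid_shape=config.grid_shape,
        obs_meta=trial_meta,
        provenance=["synthetic:scenes_trials"],
    )

    contrast_scenes = build_contrast(trial_maps)
    # implicit baseline: mean of negative trials against rest
    neg_rows = trial_meta["condition"].to_numpy() == "negative"
    implicit_data = X[neg_rows].reshape(n, config.n_trials_neg, V).mean(axis=1)
    implicit_scenes = BrainMaps(
        data=implicit_data,
        voxel_coords=coords,
        grid_shape=config.grid_shape,
        obs_meta=pd.DataFrame({"subject": subj_ids}),
        provenance=["synthetic:scenes_implicit"],
    )

    # faces task: same person-level model, independent state pattern,
    # attenuated trait signal; generated directly at the contrast level
    rng_f = _rng(config, 5)
    sem_neg = config.sigma_state / math.sqrt(config.n_trials_neg)
    sem_neu = config.sigma_state / math.sqrt(config.n_trials_neu)
    a_neg_f = (1.0 + reactivity) + rng_f.normal(0.0, sem_neg, n)
    a_neu_f = -(1.0 + reactivity) + rng_f.normal(0.0, sem_neu, n)
    bt_f = config.beta_trait_faces_ratio * config.beta_trait
    diff_f = (
        d_faces[:, None] + m_faces[:, reg] + bt_f * z[:, None] * w_trait[None, :]
    )
    sem_vox = config.sigma_noise * math.sqrt(
        1.0 / config.n_trials_neg + 1.0 / config.n_trials_neu
    )
    contrast_faces_data = (
        diff_f
        + config.beta_state * (a_neg_f - a_neu_f)[:, None] * w_state_faces[None, :]
        + rng_f.normal(0.0, sem_vox, (n, V))
    )
    implicit_faces_data = (
        person_common
        + 0.5 * diff_f
        + config.beta_state * a_neg_f[:, None] * w_state_faces[None, :]
        + rng_f.normal(0.0, config.sigma_noise / math.sqrt(config.n_trials_neg), (n, V))
    )
    subj_meta = pd.DataFrame({"subject": subj_ids})

    def _mk(data, tag):
        return BrainMaps(
            data=data,
            voxel_coords=coords,
            grid_shape=config.grid_shape,
            obs_meta=subj_meta.copy(),
            provenance=[tag],
        )

    maps = {
        ("scenes", "control"): contrast_scenes,
        ("scenes", "implicit"): implicit_scenes,
        ("faces", "control"): _mk(contrast_faces_data, "synthetic:faces_contrast"),
        ("faces", "implicit"): _mk(implicit_faces_data, "synthetic:faces_implicit"),
    }

    # traits table ----------------------------------------------------------
    rng_o = _rng(config, 6)
    rel = config.reliability_of
    na_latent = 0.5 * facet_latents["vulnerability"] + math.sqrt(0.75) * rng_t.standard_normal(n)
    stai_latent = 0.7 * facet_latents["anxiety"] + math.sqrt(0.51) * rng_t.standard_normal(n)
    bdi_latent = 0.7 * facet_latents["depression"] + math.sqrt(0.51) * rng_t.standard_normal(n)
    neuro_self = _observed(domain, rel("neuroticism"), rng_o)
    neuro_other = _observed(domain, rel("neuroticism_other"), rng_o)
    combined = (
        (neuro_self - neuro_self.mean()) / neuro_self.std()
        + (neuro_other - neuro_other.mean()) / neuro_other.std()
    )
    rating_diff = (
        ratings[:, s_c > 0].mean(axis=1) - ratings[:, s_c < 0].mean(axis=1)
    )
    traits = pd.DataFrame({"subject": subj_ids})
    traits["neuroticism"] = neuro_self
    for f in FACETS:
        traits[f] = _observed(facet_latents[f], rel(f), rng_o)
    traits["neuroticism_other"] = neuro_other
    traits["neuroticism_combined"] = 50.0 + 10.0 * combined / combined.std()
    traits["negative_affect"] = _observed(na_latent, rel("negative_affect"), rng_o)
    traits["positive_affect"] = _observed(rng_t.standard_normal(n), rel("positive_affect"), rng_o)
    traits["extraversion"] = _observed(rng_t.standard_normal(n), rel("extraversion"), rng_o)
    traits["stai"] = _observed(stai_latent, rel("stai"), rng_o)
    traits["bdi"] = _observed(bdi_latent, rel("bdi"), rng_o)
    traits["task_ratings"] = rating_diff

    truth = {
        "w_state": w_state,
        "w_state_faces": w_state_faces,
        "w_trait": w_trait,
        "latent_trait": z,
        "domain": domain,
        "global_offset": g,
        "reactivity": reactivity,
        "facet_latents": pd.DataFrame(facet_latents),
    }
    return CohortData(
        config=config,
        atlas=atlas,
        trial_maps=trial_maps,
        ratings=ratings.ravel(),
        contrast_maps=contrast_scenes,
        maps=maps,
        traits=traits,
        truth=truth,
    )


def generate_signature(
    config: SimConfig,
    kind: str,
    spatial_r: float = 0.0,
    reference: np.ndarray | None = None,
) -> SignatureMap:
    """Synthetic stand-in for a published affective neural signature.

    Returns a unit-norm voxel weight vector, optionally constructed to have
    (approximately) a requested spatial Pearson correlation with a reference
    pattern such as the cohort's true state weights.
    """
    if kind not in SIGNATURE_KINDS:
        raise ValueError(f"unknown signature kind {kind!r}; choose from {SIGNATURE_KINDS}")
    if not -1.0 <= spatial_r <= 1.0:
        raise ValueError("requested spatial correlation outside [-1, 1]")
    if spatial_r != 0.0 and reference is None:
        raise ValueError("a reference pattern is required when spatial_r != 0")
    V = config.n_voxels
    rng = _rng(config, 100 + SIGNATURE_KINDS.index(kind))
    noise = rng.standard_normal(V)
    if reference is None:
        w = noise
    elif abs(spatial_r) == 1.0:
        w = math.copysign(1.0, spatial_r) * np.asarray(reference, float)
    else:
        ref = np.asarray(reference, float)
        ref_c = (ref - ref.mean()) / ref.std()
        resid = noise - noise.mean()
        resid -= (resid @ ref_c) / (ref_c @ ref_c) * ref_c
        resid /= resid.std()
        w = spatial_r * ref_c + math.sqrt(1.0 - spatial_r**2) * resid
    w = w / np.linalg.norm(w)
    return SignatureMap(name=kind, weights=w, grid_shape=config.grid_shape)
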