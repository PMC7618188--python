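"""Synthetic lesion cohorts with known ground truth.

Clinical lesion-deficit cohorts are rarely shareable, so every downstream
stage of the pipeline is exercised against simulated cohorts engineered to
reproduce the statistical structure the analysis assumes:

* lesions are spatially structured — drawn from a small set of pathology
  archetypes emulating vascular-territory-like correlated damage, grown by
  stochastic region-growing so they are connected and irregular;
* behavioural scores degrade in proportion to each lesion's overlap with a
  planted *critical substrate*, plus Gaussian noise;
* a *decoy* region is co-lesioned with the substrate by the pathology
  process but is causally irrelevant to the score, providing the confound
  the layered block model is meant to reject.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from numba import njit
from scipy import ndimage

from .imaging import BrainTemplate, Compartment, Volume, write_volume, read_mask

#: Floor applied to synthetic scores so inverse weights 1/t are finite.
SCORE_FLOOR = 0.5

#: Number of items on the colour-word (Stroop) sheet.
STROOP_N_ITEMS = 112
STROOP_TIME_LIMIT_S = 120.0

# 26-neighbourhood offsets (Chebyshev distance 1), excluding the origin.
_NEIGHBOUR_OFFSETS = np.array(
    [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
        if (dx, dy, dz) != (0, 0, 0)
    ],
    dtype=np.int64,
)


@dataclass(frozen=True)
class PathologyArchetype:
    """A lesion-generating process biased towards one anatomical territory.

    ``seed_field`` is a probability field (non-negative, normalised over the
    brain, zero outside it) from which the lesion seed voxel is drawn; growth
    is then biased by the same field so lesions stay territory-like.
    """

    name: str
    seed_field: np.ndarray
    anisotropy: float = 0.5
    volume_median_mm3: float = 10_000.0
    volume_sigma: float = 0.7
    weight: float = 1.0

    def __post_init__(self) -> None:
        f = np.asarray(self.seed_field, dtype=np.float64)
        if (f < 0).any():
            raise ValueError("seed field must be non-negative")
        total = f.sum()
        if total <= 0:
            raise ValueError(f"degenerate archetype {self.name!r}: all-zero seed field")
        object.__setattr__(self, "seed_field", f / total)


@dataclass(frozen=True)
class SyntheticTruth:
    """Planted ground truth for parameter-recovery checks.

    ``beta`` is the score cost (score units) of lesioning the entire
    substrate; partial lesions cost ``beta`` times the overlap fraction.
    """

    substrate: np.ndarray
    decoy: np.ndarray
    beta: float = 20.0
    noise_sd: float = 5.0
    baseline_mean: float = 100.0
    baseline_sd: float = 10.0

    def __post_init__(self) -> None:
        sub = np.asarray(self.substrate).astype(bool)
        dec = np.asarray(self.decoy).astype(bool)
        if sub.shape != dec.shape:
            raise ValueError("substrate and decoy grids differ")
        if (sub & dec).any():
            raise ValueError("substrate and decoy must be disjoint")
        object.__setattr__(self, "substrate", sub)
        object.__setattr__(self, "decoy", dec)


@dataclass
class Patient:
    """One synthetic patient: lesion mask, behavioural scores, covariates."""

    id: str
    mask: np.ndarray
    scores: dict[str, float]
    group: str | None = None
    age: float | None = None
    sex: str | None = None
    education_years: float | None = None


@dataclass
class LesionCohort:
    """A cohort of patients on a shared template grid."""

    template: BrainTemplate
    patients: list[Patient]
    truth: SyntheticTruth | None = None
    seed: int | None = None

    def __len__(self) -> int:
        return len(self.patients)

    def masks(self) -> list[np.ndarray]:
        return [p.mask for p in self.patients]

    def scores(self, test: str) -> np.ndarray:
        return np.array([p.scores[test] for p in self.patients], dtype=float)

    def score_table(self) -> pd.DataFrame:
        rows = [
            {"id": p.id, "test": test, "score": score}
            for p in self.patients
            for test, score in p.scores.items()
        ]
        return pd.DataFrame(rows, columns=["id", "test", "score"])


# ---------------------------------------------------------------------------
# default desk-scale study conditions
# ---------------------------------------------------------------------------

def default_template(
    shape: tuple[int, int, int] = (24, 24, 24), voxel_size_mm: float = 4.0
) -> BrainTemplate:
    """Desk-scale brain template: an ellipsoidal brain of ~5000 voxels.

    Axis conventions: x = left->right, y = posterior->anterior,
    z = inferior->superior.  The anterior half is "frontal", the posterior
    half "posterior", each split by side; a two-voxel-thick central sagittal
    slab in the anterior half is labelled medial wall.
    """
    nx, ny, nz = shape
    cx, cy, cz = (nx - 1) / 2.0, (ny - 1) / 2.0, (nz - 1) / 2.0
    ii, jj, kk = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    semi = (0.44 * nx, 0.48 * ny, 0.44 * nz)
    brain = (
        ((ii - cx) / semi[0]) ** 2
        + ((jj - cy) / semi[1]) ** 2
        + ((kk - cz) / semi[2]) ** 2
    ) <= 1.0

    labels = np.zeros(shape, dtype=np.int16)
    anterior = jj > cy
    left = ii < cx
    medial = np.abs(ii - cx) <= 1.0
    labels[brain & anterior & left] = Compartment.LEFT_FRONTAL
    labels[brain & anterior & ~left] = Compartment.RIGHT_FRONTAL
    labels[brain & ~anterior & left] = Compartment.LEFT_POSTERIOR
    labels[brain & ~anterior & ~left] = Compartment.RIGHT_POSTERIOR
    labels[brain & anterior & medial] = Compartment.MEDIAL_WALL

    affine = np.diag([voxel_size_mm] * 3 + [1.0])
    affine[:3, 3] = -np.array([cx, cy, cz]) * voxel_size_mm
    return BrainTemplate(
        shape=shape,
        voxel_size_mm=voxel_size_mm,
        brain_mask=brain,
        labels=labels,
        affine=affine,
    )


def _gaussian_field(
    template: BrainTemplate,
    centre: tuple[float, float, float],
    sd_voxels: tuple[float, float, float],
) -> np.ndarray:
    nx, ny, nz = template.shape
    ii, jj, kk = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    q = (
        ((ii - centre[0]) / sd_voxels[0]) ** 2
        + ((jj - centre[1]) / sd_voxels[1]) ** 2
        + ((kk - centre[2]) / sd_voxels[2]) ** 2
    )
    field = np.exp(-0.5 * q)
    field[~template.brain_mask] = 0.0
    return field


def default_archetypes(template: BrainTemplate) -> list[PathologyArchetype]:
    """Vascular-territory-like archetypes with branch subterritories.

    A broad left-frontal territory elongated from the lateral convexity to
    the medial wall commonly co-lesions lateral (substrate) and medial
    (decoy) regions — the confound of interest.  Two focal branch
    archetypes (lateral pole, medial wall) emulate smaller branch-occlusion
    infarcts; patients whose lesions fall in only one branch provide the
    coverage variability that lets lesion-deficit inference tell the two
    regions apart.
    """
    nx, ny, nz = template.shape
    sx, sy, sz = nx / 24.0, ny / 24.0, nz / 24.0

    def c(x, y, z):
        return (x * sx, y * sy, z * sz)

    def s(x, y, z):
        return (x * sx, y * sy, z * sz)

    return [
        PathologyArchetype(
            "left-frontal-territory",
            _gaussian_field(template, c(7.5, 16.0, 12.5), s(4.2, 2.5, 2.5)),
            volume_median_mm3=12_000.0,
            weight=0.35,
        ),
        PathologyArchetype(
            "left-frontal-lateral-branch",
            _gaussian_field(template, c(4.5, 16.0, 12.5), s(2.0, 2.0, 2.0)),
            volume_median_mm3=7_000.0,
            weight=0.10,
        ),
        PathologyArchetype(
            "left-frontal-medial-branch",
            _gaussian_field(template, c(11.0, 16.0, 13.0), s(1.8, 2.2, 2.2)),
            volume_median_mm3=7_000.0,
            weight=0.10,
        ),
        PathologyArchetype("right-frontal-territory", _gaussian_field(template, c(16.5, 16.0, 12.5), s(3.5, 3.0, 3.0)), weight=0.15),
        PathologyArchetype("left-posterior-territory", _gaussian_field(template, c(7.0, 7.0, 11.0), s(3.5, 3.0, 3.0)), weight=0.15),
        PathologyArchetype("right-posterior-territory", _gaussian_field(template, c(16.5, 7.0, 11.0), s(3.5, 3.0, 3.0)), weight=0.15),
    ]


def default_truth(template: BrainTemplate, beta: float = 20.0) -> SyntheticTruth:
    """Lateral-frontal substrate plus a medial-wall decoy.

    With the default baseline SD of 10 score units, ``beta=20`` means a
    lesion covering the whole substrate costs ~2 SD of performance.
    """
    nx, ny, nz = template.shape
    sx, sy, sz = nx / 24.0, ny / 24.0, nz / 24.0
    ii, jj, kk = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")

    centre = (4.8 * sx, 16.0 * sy, 12.5 * sz)
    r = 2.8 * (sx * sy * sz) ** (1 / 3)
    substrate = (
        ((ii - centre[0]) ** 2 + (jj - centre[1]) ** 2 + (kk - centre[2]) ** 2)
        <= r**2
    ) & template.brain_mask

    decoy = (
        template.compartment_mask(Compartment.MEDIAL_WALL)
        & (jj >= 13.0 * sy)
        & (jj <= 19.0 * sy)
        & (kk >= 9.0 * sz)
        & (kk <= 16.0 * sz)
    )
    decoy &= ~substrate
    return SyntheticTruth(substrate=substrate, decoy=decoy, beta=beta)


# ---------------------------------------------------------------------------
# lesion growth
# ---------------------------------------------------------------------------

@njit(cache=True)
def _grow_kernel(field, brain, nx, ny, nz, seed_flat, target, anisotropy,
                 direction, rand_seed):
    """Stochastic 26-neighbourhood accretion from a seed voxel.

    Frontier voxels are absorbed with probability proportional to the
    archetype field (plus a small floor so growth can spill past the
    territory edge), modulated by a per-lesion random anisotropy direction.
    """
    np.random.seed(rand_seed)
    nvox = nx * ny * nz
    lesion = np.zeros(nvox, dtype=np.uint8)
    lesion[seed_flat] = 1
    floor = field.max() * 1e-3
    si = seed_flat // (ny * nz)
    sj = (seed_flat // nz) % ny
    sk = seed_flat % nz

    cap = min(nvox, target * 32 + 64)
    frontier = np.empty(cap, dtype=np.int64)
    weights = np.empty(cap, dtype=np.float64)
    in_frontier = np.zeros(nvox, dtype=np.uint8)
    n_front = 0
    size = 1
    current = seed_flat
    while True:
        # push unvisited in-brain neighbours of `current`
        ci = current // (ny * nz)
        cj = (current // nz) % ny
        ck = current % nz
        for di in range(-1, 2):
            for dj in range(-1, 2):
                for dk in range(-1, 2):
                    if di == 0 and dj == 0 and dk == 0:
                        continue
                    i = ci + di
                    j = cj + dj
                    k = ck + dk
                    if i < 0 or j < 0 or k < 0 or i >= nx or j >= ny or k >= nz:
                        continue
                    f = (i * ny + j) * nz + k
                    if lesion[f] == 1 or brain[f] == 0 or in_frontier[f] == 1:
                        continue
                    if n_front >= cap:
                        continue
                    ri = i - si
                    rj = j - sj
                    rk = k - sk
                    norm = math.sqrt(ri * ri + rj * rj + rk * rk)
                    aniso = 1.0
                    if norm > 0:
                        dot = (ri * direction[0] + rj * direction[1] + rk * direction[2]) / norm
                        aniso = math.exp(anisotropy * dot)
                    frontier[n_front] = f
                    weights[n_front] = (field[f] + floor) * aniso
                    in_frontier[f] = 1
                    n_front += 1
        if size >= target or n_front == 0:
            break
        # sample a frontier voxel proportionally to weight
        total = 0.0
        for q in range(n_front):
            total += weights[q]
        u = np.random.random() * total
        acc = 0.0
        pick = n_front - 1
        for q in range(n_front):
            acc += weights[q]
            if acc >= u:
                pick = q
                break
        current = frontier[pick]
        # swap-delete the pick
        n_front -= 1
        frontier[pick] = frontier[n_front]
        weights[pick] = weights[n_front]
        in_frontier[current] = 0
        lesion[current] = 1
        size += 1
    return lesion


def _grow_lesion(
    rng: np.random.Generator,
    template: BrainTemplate,
    archetype: PathologyArchetype,
    target_voxels: int,
) -> np.ndarray:
    field = archetype.seed_field
    seed_flat = int(rng.choice(field.size, p=field.ravel()))
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    nx, ny, nz = template.shape
    lesion = _grow_kernel(
        field.ravel(),
        template.brain_mask.ravel().astype(np.uint8),
        nx, ny, nz,
        seed_flat,
        int(target_voxels),
        float(archetype.anisotropy),
        direction.astype(np.float64),
        int(rng.integers(2**31)),
    )
    return lesion.reshape(template.shape).astype(bool)


def overlap_fraction(mask: np.ndarray, region: np.ndarray) -> float:
    """Fraction of ``region`` voxels covered by ``mask``."""
    region = np.asarray(region).astype(bool)
    n = int(region.sum())
    if n == 0:
        return 0.0
    return float((np.asarray(mask).astype(bool) & region).sum()) / n


def assign_scores(
    masks: list[np.ndarray], truth: SyntheticTruth, seed: int
) -> list[float]:
    """Scores degraded in proportion to substrate overlap.

    ``score_k = max(eps, baseline_k - beta * overlap_k + noise_k)`` with
    ``baseline_k ~ N(mean, SD)`` and ``noise_k ~ N(0, noise SD)``; the floor
    ``eps = 0.5`` keeps inverse weights 1/t finite.
    """
    rng = np.random.default_rng(seed)
    scores = []
    for mask in masks:
        if np.asarray(mask).shape != truth.substrate.shape:
            raise ValueError("mask grid does not match truth grid")
        baseline = rng.normal(truth.baseline_mean, truth.baseline_sd)
        noise = rng.normal(0.0, truth.noise_sd) if truth.noise_sd > 0 else 0.0
        overlap = overlap_fraction(mask, truth.substrate)
        scores.append(max(SCORE_FLOOR, baseline - truth.beta * overlap + noise))
    return scores


def generate_cohort(
    template: BrainTemplate,
    archetypes: list[PathologyArchetype],
    truth: SyntheticTruth,
    n_patients: int,
    seed: int,
    test_names: tuple[str, ...] = ("stroop",),
) -> LesionCohort:
    """Generate a reproducible synthetic cohort.

    Each lesion samples an archetype, a seed voxel from its field, and a
    target volume from its log-normal volume distribution, then grows by
    stochastic accretion.  Scores per test follow :func:`assign_scores`.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    for arch in archetypes:
        if arch.seed_field.shape != template.shape:
            raise ValueError(f"archetype {arch.name!r} grid does not match template")
    if truth.substrate.shape != template.shape:
        raise ValueError("truth grid does not match template")

    root = np.random.SeedSequence(seed)
    grow_seed, score_root, cov_seed = root.spawn(3)
    rng = np.random.default_rng(grow_seed)
    voxel_mm3 = template.voxel_size_mm**3

    arch_p = np.array([a.weight for a in archetypes], dtype=float)
    if (arch_p <= 0).all():
        raise ValueError("archetype weights must include a positive entry")
    arch_p /= arch_p.sum()
    masks = []
    for _ in range(n_patients):
        arch = archetypes[rng.choice(len(archetypes), p=arch_p)]
        vol_mm3 = arch.volume_median_mm3 * np.exp(rng.normal(0.0, arch.volume_sigma))
        target = int(np.clip(round(vol_mm3 / voxel_mm3), 2, template.n_brain_voxels // 4))
        masks.append(_grow_lesion(rng, template, arch, target))

    score_seeds = score_root.generate_state(len(test_names))
    all_scores = {
        test: assign_scores(masks, truth, int(s) % (2**31))
        for test, s in zip(test_names, score_seeds)
    }

    cov_rng = np.random.default_rng(cov_seed)
    patients = []
    for k, mask in enumerate(masks):
        patients.append(
            Patient(
                id=f"sub-{k:04d}",
                mask=mask,
                scores={t: all_scores[t][k] for t in test_names},
                age=float(np.clip(cov_rng.normal(48.0, 15.0), 18, 80)),
                sex="F" if cov_rng.random() < 0.5 else "M",
                education_years=float(np.clip(cov_rng.normal(15.0, 3.0), 8, 24)),
            )
        )
    return LesionCohort(template=template, patients=patients, truth=truth, seed=seed)


def decoy_confound_correlation(cohort: LesionCohort) -> float:
    """Pearson correlation, over patients, of substrate vs decoy involvement.

    Quantifies how strongly the pathology process co-lesions the planted
    substrate and the decoy — the confound the layered model must reject.
    """
    if cohort.truth is None:
        raise ValueError("cohort has no embedded ground truth")
    sub = np.array([overlap_fraction(m, cohort.truth.substrate) for m in cohort.masks()])
    dec = np.array([overlap_fraction(m, cohort.truth.decoy) for m in cohort.masks()])
    if sub.std() == 0 or dec.std() == 0:
        return 0.0
    return float(np.corrcoef(sub, dec)[0, 1])


# ---------------------------------------------------------------------------
# pseudo-meta-analytic z map
# ---------------------------------------------------------------------------

def make_meta_map(
    template: BrainTemplate,
    target_mask: np.ndarray,
    peak_z: float = 6.0,
    smoothing_fwhm_mm: float = 8.0,
    seed: int = 0,
    background_sd: float = 0.6,
) -> Volume:
    """Smooth pseudo meta-analytic z map peaking on ``target_mask``.

    Emulates a term-based meta-analytic activation map: a smooth focus of
    suprathreshold z values on the target plus smooth sub-threshold
    background noise, zero outside the brain.
    """
    if peak_z <= 3.1:
        raise ValueError("peak_z must exceed the z > 3.1 ROI threshold")
    target = np.asarray(target_mask).astype(float)
    if target.shape != template.shape:
        raise ValueError("target grid does not match template")
    if target.sum() and not (np.asarray(target_mask).astype(bool) & template.brain_mask).any():
        raise ValueError("target mask lies outside the brain")

    sigma_vox = smoothing_fwhm_mm / (2.3548 * template.voxel_size_mm)
    rng = np.random.default_rng(seed)
    noise = ndimage.gaussian_filter(rng.normal(size=template.shape), sigma_vox)
    sd = noise[template.brain_mask].std()
    background = noise / sd * background_sd if sd > 0 else noise

    zmap = background.copy()
    if target.sum() > 0:
        focus = ndimage.gaussian_filter(target, sigma_vox)
        zmap = zmap + focus / focus.max() * peak_z
    zmap[~template.brain_mask] = 0.0
    return Volume(data=zmap, affine=template.affine, kind="zscore")


# ---------------------------------------------------------------------------
# behavioural scoring rules
# ---------------------------------------------------------------------------

def prorate_stroop(raw_correct: int, elapsed_s: float) -> float:
    """Prorated colour-word score.

    A participant naming all 112 ink colours in under two minutes is
    credited with the count they would have reached in the full two
    minutes; otherwise the raw count stands.
    """
    if elapsed_s <= 0:
        raise ValueError("elapsed_s must be positive")
    if not (0 <= raw_correct <= STROOP_N_ITEMS):
        raise ValueError(f"raw_correct must lie in [0, {STROOP_N_ITEMS}]")
    if raw_correct == STROOP_N_ITEMS and elapsed_s < STROOP_TIME_LIMIT_S:
        return STROOP_N_ITEMS * STROOP_TIME_LIMIT_S / elapsed_s
    return float(raw_correct)


def classify_impairment(score: float, normative_percentile_table: dict) -> bool:
    """Impaired iff the score falls strictly below the 5th-percentile cut-off."""
    if not normative_percentile_table or 5 not in normative_percentile_table:
        raise ValueError("normative table must supply the 5th-percentile cut-off")
    return score < normative_percentile_table[5]


# ---------------------------------------------------------------------------
# cohort I/O
# ---------------------------------------------------------------------------

def write_cohort(cohort: LesionCohort, out_dir) -> None:
    """Write one NIfTI mask per patient, a score table, truth and config."""
    out = Path(out_dir)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    affine = cohort.template.affine
    for p in cohort.patients:
        write_volume(
            Volume(p.mask.astype(np.uint8), affine, kind="mask"),
            out / "masks" / f"{p.id}.nii.gz",
        )
    cohort.score_table().to_csv(out / "scores.csv", index=False)
    write_volume(
        Volume(cohort.template.brain_mask.astype(np.uint8), affine, kind="mask"),
        out / "brain_mask.nii.gz",
    )
    write_volume(
        Volume(cohort.template.labels.astype(float), affine, kind="labels"),
        out / "compartments.nii.gz",
    )
    if cohort.truth is not None:
        write_volume(Volume(cohort.truth.substrate.astype(np.uint8), affine, "mask"), out / "truth_substrate.nii.gz")
        write_volume(Volume(cohort.truth.decoy.astype(np.uint8), affine, "mask"), out / "truth_decoy.nii.gz")
    config = {
        "seed": cohort.seed,
        "n_patients": len(cohort),
        "voxel_size_mm": cohort.template.voxel_size_mm,
        "shape": list(cohort.template.shape),
    }
    (out / "cohort_config.json").write_text(json.dumps(config, indent=2))


def load_cohort(in_dir, template: BrainTemplate) -> LesionCohort:
    """Load a cohort written by :func:`write_cohort` (or user-supplied data)."""
    src = Path(in_dir)
    score_path = src / "scores.csv"
    if not score_path.exists():
        raise FileNotFoundError(f"missing score table: {score_path}")
    table = pd.read_csv(score_path)
    patients = []
    for pid, group in table.groupby("id", sort=True):
        mask = read_mask(src / "masks" / f"{pid}.nii.gz")
        patients.append(
            Patient(
                id=str(pid),
                mask=mask.astype_bool(),
                scores=dict(zip(group["test"], group["score"])),
            )
        )
    return LesionCohort(template=template, patients=patients)
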