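"""Synthetic ground-truth data generator.

Every downstream stage of the pipeline (composition statistics, metabolic
penalty post-processing, image quantification) is exercised on data produced
here, with the generating parameters recorded in a :class:`GroundTruth` so
that recovery tests can compare estimates against known truth.

The generator emulates three kinds of input:

* a per-cell table of brain immune cells (microglia, two border-associated
  macrophage subsets BAM1/BAM2, dendritic cells) from healthy and AD donors,
  with an AD-dependent multiplicative depletion of the BAM2 subset and a
  Braak-stage-linked multiplicative decline of the BAM2 fraction;
* a reaction x sample matrix of non-negative metabolic reaction penalties
  (log-normally distributed, lower penalty = higher flux capacity) with
  condition- and cell-type-specific shifts concentrated in designated
  subsystems;
* multi-channel fluorescence z-stacks containing curvilinear bright vessels
  and blob-like amyloid plaques over a smooth background, with a controlled
  fraction of plaque overlapping the vessel mask and Poisson-Gaussian noise.

All randomness flows from a single seed; per-component sub-streams are
derived deterministically so that, e.g., the clinical table for a dataset is
identical whether it is generated before or after the cell table.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "CoverageInfeasibleError",
    "gen_cell_table",
    "gen_clinical",
    "gen_penalty_matrix",
    "gen_image_stack",
    "write_ground_truth",
]

CELL_TYPES = ("microglia", "BAM1", "BAM2", "DC")
CONDITIONS = ("healthy", "AD")

# sub-stream tags: each generator component draws from default_rng([seed, tag])
_STREAM_PATIENTS = 1
_STREAM_CLINICAL = 2
_STREAM_CELLS = 3
_STREAM_PENALTY = 4
_STREAM_IMAGE = 5


class CoverageInfeasibleError(RuntimeError):
    """Plaque-on-vessel coverage target could not be met for the geometry."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of one synthetic dataset.

    Proportions refer to the healthy baseline composition of the brain
    immune landscape; AD and Braak effects act multiplicatively on the BAM2
    proportion before renormalisation and cell sampling.
    """

    seed: int = 0
    n_patients_per_condition: int = 40
    cells_per_patient_range: tuple[int, int] = (500, 2000)
    base_proportions: Mapping[str, float] = field(
        default_factory=lambda: {
            "microglia": 0.85,
            "BAM1": 0.06,
            "BAM2": 0.05,
            "DC": 0.04,
        }
    )
    bam2_ad_depletion_fold: float = 2.0
    braak_fold_per_step: float = 2.0
    n_reactions: int = 90
    subsystem_sizes: Sequence[int] = (10,) * 9
    penalty_location: float = 0.0
    penalty_scale: float = 0.5
    shift_map: Mapping[tuple[str, str], float] = field(default_factory=dict)
    image_shape: tuple[int, int, int] = (8, 256, 256)
    n_vessels: int = 4
    vessel_width_px: int = 7
    n_plaques: int = 40
    plaque_radius_px: int = 4
    plaque_on_vessel_target: float = 0.2
    snr: float = 10.0
    pixel_size_um: float = 1.0

    def __post_init__(self) -> None:
        total = float(sum(self.base_proportions.values()))
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"base_proportions must sum to 1, got {total!r}")
        if self.bam2_ad_depletion_fold <= 0 or self.braak_fold_per_step <= 0:
            raise ValueError("fold parameters must be positive")
        if not (0.0 <= self.plaque_on_vessel_target <= 1.0):
            raise ValueError("plaque_on_vessel_target must lie in [0, 1]")
        if self.penalty_scale < 0:
            raise ValueError("penalty_scale must be non-negative")
        if any(s < 1 for s in self.subsystem_sizes):
            raise ValueError("subsystem_sizes must all be >= 1")
        if sum(self.subsystem_sizes) != self.n_reactions:
            raise ValueError(
                "subsystem_sizes must sum to n_reactions "
                f"({sum(self.subsystem_sizes)} != {self.n_reactions})"
            )
        if self.snr <= 0:
            raise ValueError("snr must be positive")
        if any(d <= 0 for d in self.image_shape):
            raise ValueError("image_shape must be positive")
        lo, hi = self.cells_per_patient_range
        if not (1 <= lo <= hi):
            raise ValueError("cells_per_patient_range must be a valid interval")


@dataclass
class GroundTruth:
    """Generator-side record of every true quantity used by recovery tests."""

    patient_fractions: pd.DataFrame | None = None  # patients x cell types, realized
    patient_expected_proportions: pd.DataFrame | None = None  # pre-sampling truth
    subsystem_shifts: dict[str, float] = field(default_factory=dict)
    vessel_area_px: int | None = None
    plaque_on_vessel_pct: float | None = None
    particle_count: int | None = None
    # noiseless masks kept in memory for self-consistency checks; not serialized
    vessel_mask: np.ndarray | None = None
    plaque_mask: np.ndarray | None = None

    def to_dict(self) -> dict:
        out: dict = {"subsystem_shifts": dict(self.subsystem_shifts)}
        if self.patient_fractions is not None:
            out["patient_fractions"] = self.patient_fractions.to_dict()
        if self.patient_expected_proportions is not None:
            out["patient_expected_proportions"] = (
                self.patient_expected_proportions.to_dict()
            )
        for k in ("vessel_area_px", "plaque_on_vessel_pct", "particle_count"):
            v = getattr(self, k)
            if v is not None:
                out[k] = v
        return out


def write_ground_truth(gt: GroundTruth, path) -> None:
    with open(path, "w") as fh:
        json.dump(gt.to_dict(), fh, indent=1, default=float)


# ---------------------------------------------------------------------------
# patients and clinical covariates
# ---------------------------------------------------------------------------

def _patient_roster(config: SyntheticConfig) -> pd.DataFrame:
    """Balanced healthy/AD patient list; deterministic in config.seed."""
    n = config.n_patients_per_condition
    ids = [f"P{i:03d}" for i in range(2 * n)]
    condition = ["healthy"] * n + ["AD"] * n
    return pd.DataFrame({"patient_id": ids, "condition": condition})


# AD donors carry more advanced neurofibrillary pathology: Braak mass rises
# linearly with stage in AD, flat in healthy donors.
_BRAAK_W_HEALTHY = np.ones(7) / 7.0
_BRAAK_W_AD = np.arange(1, 8) / np.arange(1, 8).sum()
_CERAD_W_HEALTHY = np.array([0.5, 0.3, 0.15, 0.05])
_CERAD_W_AD = np.array([0.05, 0.15, 0.3, 0.5])


def gen_clinical(
    config: SyntheticConfig, patients: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Per-patient clinical covariates.

    sex ~ Bernoulli(0.5); Braak uniform 0-6 in healthy, linearly up-weighted
    toward high stages in AD; PMI ~ Gamma(shape 3, scale 3) hours; CERAD
    ordinal 0-3 (mass at low values in healthy, high in AD); education years
    ~ round(Normal(16, 3)) clipped to [8, 25]; APOE allele counts
    e2 ~ Binomial(2, 0.08) and e4 ~ Binomial(2, 0.15 healthy / 0.35 AD).

    The returned Braak stages are the ones :func:`gen_cell_table` couples to
    the per-patient BAM2 proportion (multiplied by
    ``braak_fold_per_step ** -braak`` before sampling), so the same config
    yields a consistent pair of tables regardless of call order.
    """
    if patients is None:
        patients = _patient_roster(config)
    rng = np.random.default_rng([config.seed, _STREAM_CLINICAL])
    n = len(patients)
    is_ad = (patients["condition"] == "AD").to_numpy()
    braak = np.empty(n, dtype=int)
    cerad = np.empty(n, dtype=int)
    e4 = np.empty(n, dtype=int)
    sex = rng.integers(0, 2, size=n)
    pmi = rng.gamma(3.0, 3.0, size=n)
    education = np.clip(np.rint(rng.normal(16.0, 3.0, size=n)), 8, 25).astype(int)
    e2 = rng.binomial(2, 0.08, size=n)
    for i in range(n):
        braak[i] = rng.choice(7, p=_BRAAK_W_AD if is_ad[i] else _BRAAK_W_HEALTHY)
        cerad[i] = rng.choice(4, p=_CERAD_W_AD if is_ad[i] else _CERAD_W_HEALTHY)
        e4[i] = rng.binomial(2, 0.35 if is_ad[i] else 0.15)
    return pd.DataFrame(
        {
            "patient_id": patients["patient_id"].to_numpy(),
            "condition": patients["condition"].to_numpy(),
            "sex": sex,
            "braak": braak,
            "pmi": pmi,
            "cerad": cerad,
            "education": education,
            "apoe_e2": e2,
            "apoe_e4": e4,
        }
    )


# ---------------------------------------------------------------------------
# cell table
# ---------------------------------------------------------------------------

def _patient_proportions(config: SyntheticConfig, clinical: pd.DataFrame) -> pd.DataFrame:
    """True pre-sampling cell-type proportions per patient.

    The BAM2 proportion is exactly ``base / bam2_ad_depletion_fold`` in AD
    (and further divided by ``braak_fold_per_step`` per Braak stage); the
    other cell types share the complement in their base ratio. Keeping the
    realized BAM2 proportion exactly log-linear in the fold parameters makes
    the generated fold effects exact rather than approximate.
    """
    base = np.array([config.base_proportions[ct] for ct in CELL_TYPES])
    bam2_ix = CELL_TYPES.index("BAM2")
    base_rest = base.sum() - base[bam2_ix]
    rows = []
    for _, row in clinical.iterrows():
        p = base.copy()
        if row["condition"] == "AD":
            p[bam2_ix] /= config.bam2_ad_depletion_fold
        p[bam2_ix] /= config.braak_fold_per_step ** row["braak"]
        if p[bam2_ix] >= 1.0:
            raise ValueError("BAM2 proportion reaches 1; fold parameters invalid")
        if base_rest <= 0 and p[bam2_ix] < 1.0:
            raise ValueError("cell-type proportions renormalise to zero")
        scale = (1.0 - p[bam2_ix]) / base_rest
        for i in range(len(p)):
            if i != bam2_ix:
                p[i] = base[i] * scale
        rows.append(p)
    return pd.DataFrame(rows, index=clinical["patient_id"], columns=CELL_TYPES)


def gen_cell_table(
    config: SyntheticConfig,
) -> tuple[pd.DataFrame, GroundTruth]:
    """One row per cell: cell_id, patient_id, condition, cluster.

    Patients are assigned conditions in balance; per-patient cell counts are
    uniform over ``cells_per_patient_range``; labels are multinomial draws
    from the condition- and Braak-adjusted proportions. The GroundTruth
    records both the true pre-sampling proportions and the realized
    fractions.
    """
    clinical = gen_clinical(config)
    props = _patient_proportions(config, clinical)
    rng = np.random.default_rng([config.seed, _STREAM_CELLS])
    lo, hi = config.cells_per_patient_range
    n_cells = rng.integers(lo, hi + 1, size=len(clinical))

    pat_ids, conds, labels = [], [], []
    realized = np.zeros((len(clinical), len(CELL_TYPES)))
    for i, (_, row) in enumerate(clinical.iterrows()):
        counts = rng.multinomial(n_cells[i], props.iloc[i].to_numpy())
        realized[i] = counts / counts.sum()
        for ct, c in zip(CELL_TYPES, counts):
            labels.append(np.repeat(ct, c))
        pat_ids.append(np.repeat(row["patient_id"], n_cells[i]))
        conds.append(np.repeat(row["condition"], n_cells[i]))
    labels = np.concatenate(labels) if labels else np.array([], dtype=object)
    pat_ids = np.concatenate(pat_ids) if pat_ids else np.array([], dtype=object)
    conds = np.concatenate(conds) if conds else np.array([], dtype=object)
    cells = pd.DataFrame(
        {
            "cell_id": [f"C{i:07d}" for i in range(len(labels))],
            "patient_id": pd.Categorical(pat_ids),
            "condition": pd.Categorical(conds, categories=list(CONDITIONS)),
            "cluster": pd.Categorical(labels, categories=list(CELL_TYPES)),
        }
    )
    gt = GroundTruth(
        patient_fractions=pd.DataFrame(
            realized, index=props.index, columns=CELL_TYPES
        ),
        patient_expected_proportions=props,
    )
    return cells, gt


# ---------------------------------------------------------------------------
# penalty matrix
# ---------------------------------------------------------------------------

def gen_penalty_matrix(
    config: SyntheticConfig, cell_labels: pd.DataFrame
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame, GroundTruth]:
    """Log-normal reaction penalties with condition/cell-type shifts.

    ``cell_labels`` needs columns ``sample_id``, ``cell_type``, ``condition``
    (one row per sample; samples may be cells or metacells). Penalties are
    ``exp(Normal(location + shift, scale))`` where the shift from
    ``config.shift_map[(subsystem, cell_type)]`` is applied only to AD
    samples of that cell type, on every reaction of that subsystem.

    Returns (penalties reactions x samples, reaction->subsystem map,
    sample annotation copy, GroundTruth).
    """
    required = {"sample_id", "cell_type", "condition"}
    missing = required - set(cell_labels.columns)
    if missing:
        raise ValueError(f"cell_labels missing columns: {sorted(missing)}")
    rng = np.random.default_rng([config.seed, _STREAM_PENALTY])
    subsystems = []
    for i, size in enumerate(config.subsystem_sizes):
        subsystems.extend([f"SS{i:02d}"] * size)
    reaction_ids = [f"R{i:04d}" for i in range(config.n_reactions)]
    submap = pd.Series(subsystems, index=reaction_ids, name="subsystem")

    n_samp = len(cell_labels)
    loc = np.full((config.n_reactions, n_samp), config.penalty_location)
    is_ad = (cell_labels["condition"] == "AD").to_numpy()
    for (ss, ct), shift in config.shift_map.items():
        r_mask = (submap == ss).to_numpy()
        c_mask = is_ad & (cell_labels["cell_type"] == ct).to_numpy()
        loc[np.ix_(r_mask, c_mask)] += shift
    values = np.exp(rng.normal(loc, config.penalty_scale))
    pm = pd.DataFrame(values, index=reaction_ids,
                      columns=cell_labels["sample_id"].to_numpy())
    gt = GroundTruth(
        subsystem_shifts={f"{ss}|{ct}": float(v)
                          for (ss, ct), v in config.shift_map.items()}
    )
    return pm, submap, cell_labels.copy(), gt


# ---------------------------------------------------------------------------
# image stacks
# ---------------------------------------------------------------------------

def _disk_offsets(radius: int) -> tuple[np.ndarray, np.ndarray]:
    yy, xx = np.mgrid[-radius:radius + 1, -radius:radius + 1]
    inside = yy**2 + xx**2 <= radius**2
    return yy[inside], xx[inside]


def _paint_disk(mask: np.ndarray, cy: int, cx: int, dy: np.ndarray, dx: np.ndarray) -> None:
    y = cy + dy
    x = cx + dx
    ok = (y >= 0) & (y < mask.shape[0]) & (x >= 0) & (x < mask.shape[1])
    mask[y[ok], x[ok]] = True


def _vessel_mask(config: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    """Curvilinear tubes: biased random walks across the frame, dilated to width."""
    _, ny, nx = config.image_shape
    mask = np.zeros((ny, nx), dtype=bool)
    dy_off, dx_off = _disk_offsets(max(1, config.vessel_width_px // 2))
    for _ in range(config.n_vessels):
        # start on a random edge, head roughly toward the opposite edge
        vertical = rng.integers(0, 2) == 0
        if vertical:
            y, x = 0.0, float(rng.uniform(0.1, 0.9) * nx)
            heading = np.pi / 2  # downward
        else:
            y, x = float(rng.uniform(0.1, 0.9) * ny), 0.0
            heading = 0.0  # rightward
        steps = int(1.5 * max(ny, nx))
        for _ in range(steps):
            _paint_disk(mask, int(round(y)), int(round(x)), dy_off, dx_off)
            heading += rng.normal(0.0, 0.15)
            y += np.sin(heading)
            x += np.cos(heading)
            if not (0 <= y < ny and 0 <= x < nx):
                break
    return mask


def _place_plaques(
    config: SyntheticConfig, vessel: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Plaque mask meeting the plaque-on-vessel coverage target (+-1 pp)."""
    ny, nx = vessel.shape
    target = config.plaque_on_vessel_target
    vessel_area = int(vessel.sum())
    if vessel_area == 0 and target > 0:
        raise CoverageInfeasibleError("no vessel pixels but nonzero coverage target")
    plaque = np.zeros_like(vessel)
    dy_off, dx_off = _disk_offsets(config.plaque_radius_px)
    vy, vx = np.nonzero(vessel)

    def coverage() -> float:
        return (plaque & vessel).sum() / vessel_area if vessel_area else 0.0

    budget = max(1000, 10 * config.n_plaques + 2 * vessel_area)
    placed = 0
    iters = 0
    # phase 1: on-vessel plaques until the target is met; near the target,
    # pick among a few candidate centers the one landing closest to it
    while target > 0 and coverage() < target - 0.001:
        iters += 1
        if iters > budget:
            raise CoverageInfeasibleError(
                f"coverage target {target:.0%} not reached within iteration budget"
            )
        uncovered = vessel & ~plaque
        uy, ux = np.nonzero(uncovered)
        if len(uy) == 0:
            break
        picks = rng.integers(0, len(uy), size=min(8, len(uy)))
        best, best_gap = None, None
        for j in picks:
            trial = plaque.copy()
            _paint_disk(trial, int(uy[j]), int(ux[j]), dy_off, dx_off)
            cov = (trial & vessel).sum() / vessel_area
            gap = abs(cov - target) if cov >= target else target - cov
            if best_gap is None or gap < best_gap:
                best, best_gap = trial, gap
        plaque = best
        placed += 1
    if vessel_area and abs(coverage() - target) > 0.01:
        raise CoverageInfeasibleError(
            f"realized coverage {coverage():.1%} misses target {target:.0%} by >1 pp"
        )
    # phase 2: remaining plaques strictly off the vessel mask
    n_off = max(0, config.n_plaques - placed)
    attempts = 0
    while n_off > 0 and attempts < budget:
        attempts += 1
        cy = int(rng.integers(0, ny))
        cx = int(rng.integers(0, nx))
        trial = np.zeros_like(plaque)
        _paint_disk(trial, cy, cx, dy_off, dx_off)
        if not (trial & vessel).any():
            plaque |= trial
            n_off -= 1
    return plaque


def gen_image_stack(
    config: SyntheticConfig,
) -> tuple[np.ndarray, GroundTruth]:
    """Two-channel z-stack (channel 0 vessel, channel 1 plaque).

    Signal amplitudes: vessels and plaques at 200 counts over a smooth
    low-frequency background (amplitude ~20); each structure channel has a
    Gaussian z-profile peaking at 1 on a random central slice so a maximum
    projection recovers the full-amplitude plane. Noise is Poisson shot
    noise on the expected signal plus additive Gaussian read noise with
    sigma = peak / snr.

    Returns (stack with shape (2, z, y, x), GroundTruth with the exact
    noiseless vessel area, plaque-on-vessel coverage %, and plaque particle
    count).
    """
    rng = np.random.default_rng([config.seed, _STREAM_IMAGE])
    nz, ny, nx = config.image_shape
    vessel = _vessel_mask(config, rng)
    plaque = _place_plaques(config, vessel, rng)

    peak = 200.0
    yy, xx = np.mgrid[0:ny, 0:nx]
    background = 20.0 * (
        0.5
        + 0.25 * np.sin(2 * np.pi * yy / ny + rng.uniform(0, 2 * np.pi))
        + 0.25 * np.cos(2 * np.pi * xx / nx + rng.uniform(0, 2 * np.pi))
    )

    def z_profile() -> np.ndarray:
        z0 = rng.uniform(0.3, 0.7) * (nz - 1)
        z = np.arange(nz)
        w = np.exp(-0.5 * ((z - z0) / max(1.0, nz / 4)) ** 2)
        return w / w.max()

    stack = np.empty((2, nz, ny, nx))
    sigma_read = peak / config.snr
    for c, m in enumerate((vessel, plaque)):
        w = z_profile()
        signal = peak * m.astype(float)
        for z in range(nz):
            expected = background + w[z] * signal
            stack[c, z] = rng.poisson(expected) + rng.normal(0.0, sigma_read, (ny, nx))
    stack = np.clip(stack, 0.0, None)

    from scipy import ndimage

    vessel_area = int(vessel.sum())
    n_particles = int(ndimage.label(plaque, structure=np.ones((3, 3)))[1])
    coverage_pct = (
        100.0 * (plaque & vessel).sum() / vessel_area if vessel_area else 0.0
    )
    gt = GroundTruth(
        vessel_area_px=vessel_area,
        plaque_on_vessel_pct=float(coverage_pct),
        particle_count=n_particles,
        vessel_mask=vessel,
        plaque_mask=plaque,
    )
    return stack, gt


# ---------------------------------------------------------------------------
# serialization helpers
# ---------------------------------------------------------------------------

def write_tables(outdir, cells: pd.DataFrame | None = None,
                 clinical: pd.DataFrame | None = None,
                 penalties: pd.DataFrame | None = None,
                 subsystem_map: pd.Series | None = None) -> None:
    """Write generated tables as comma-separated text with header rows."""
    import pathlib

    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if cells is not None:
        cells.to_csv(outdir / "cells.csv", index=False)
    if clinical is not None:
        clinical.to_csv(outdir / "clinical.csv", index=False)
    if penalties is not None:
        penalties.to_csv(outdir / "penalties.csv")
    if subsystem_map is not None:
        subsystem_map.rename_axis("reaction_id").to_csv(outdir / "subsystems.csv")


def write_image_stack(stack: np.ndarray, path, pixel_size_um: float = 1.0) -> None:
    """Multi-page TIFF, channel-first then z (page order: c0z0, c0z1, ...)."""
    import tifffile

    pages = stack.reshape(-1, *stack.shape[-2:]).astype(np.float32)
    tifffile.imwrite(
        path,
        pages,
        metadata={
            "axes": "QYX",
            "channels": int(stack.shape[0]),
            "zslices": int(stack.shape[1]),
            "pixel_size_um": pixel_size_um,
            "page_order": "channel-major (all z of channel 0, then channel 1)",
        },
    )


def read_image_stack(path) -> tuple[np.ndarray, float]:
    import tifffile

    with tifffile.TiffFile(path) as tf:
        pages = tf.asarray()
        meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
    nc = int(meta.get("channels", 1))
    nz = int(meta.get("zslices", pages.shape[0] // nc))
    px = float(meta.get("pixel_size_um", 1.0))
    return pages.reshape(nc, nz, *pages.shape[-2:]), px
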