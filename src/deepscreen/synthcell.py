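"""Ground-truthed synthetic flow-cell experiments.

A deep-screening run images the same flow cell repeatedly while an antigen
titration and a wash series are applied.  Every sequenced cluster is a clonal
DNA colony identified by a random 28-mer UMI; each clone is laid down at
``redundancy`` distinct locations so that per-clone statistics can be computed
downstream.  This module generates the whole experiment from a truth table:

* a clone library with known dissociation constants and display efficiencies,
* cluster coordinates on one or more tiles,
* per-condition tile images (a normalization channel where every cluster
  fluoresces at a common level, and a binding channel that follows the
  equilibrium and biphasic-dissociation forward models),
* CDR read tables with optional substitution errors.

All stochastic draws descend from one integer seed via numpy's seed-sequence
spawning, so identical seeds give byte-identical outputs.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile

AA20 = "ACDEFGHIKLMNPQRSTVWY"
UMI_LENGTH = 28
DNA = "ACGT"

DEFAULT_TILE_SHAPE = (512, 512)  # desk-scale stand-in for 2,048 x 160,000 px scans
DEFAULT_REDUNDANCY = 12          # every UMI must appear at least 12 times
DEFAULT_PSF_SIGMA = 1.0          # rendered cluster width, px (~1 um clusters)
DEFAULT_BACKGROUND = 100.0
DEFAULT_FMAX = 1000.0
DEFAULT_FMIN = 100.0

# The two assay schedules used throughout: a 4-point lysozyme titration with
# washes read at 5-120 min, and a 7-point HER2 titration.
HEL_CONCENTRATIONS = (1e-9, 10e-9, 100e-9, 300e-9)
HEL_WASH_TIMES = (300.0, 600.0, 900.0, 1200.0, 1800.0, 3600.0, 7200.0)
HER2_CONCENTRATIONS = (100e-12, 333e-12, 1e-9, 3.33e-9, 10e-9, 33.3e-9, 100e-9)
HER2_WASH_TIMES = (300.0, 600.0, 1200.0, 3600.0, 14400.0, 25200.0)


@dataclass(frozen=True)
class AssaySchedule:
    """Ordered antigen concentrations (molar) and wash read times (seconds)."""

    concentrations: tuple = HEL_CONCENTRATIONS
    wash_times: tuple = HEL_WASH_TIMES
    normalization_channel: str = "C"
    binding_channel: str = "T"

    def __post_init__(self):
        concs = tuple(float(c) for c in self.concentrations)
        washes = tuple(float(t) for t in self.wash_times)
        if any(c <= 0 for c in concs):
            raise ValueError("concentrations must be positive molar values")
        if list(concs) != sorted(set(concs)):
            raise ValueError("concentrations must be strictly increasing")
        if list(washes) != sorted(set(washes)):
            raise ValueError("wash_times must be strictly increasing")
        object.__setattr__(self, "concentrations", concs)
        object.__setattr__(self, "wash_times", washes)

    def condition_ids(self):
        ids = [f"eq_{c:.3g}M" for c in self.concentrations]
        ids += [f"wash_{int(t)}s" for t in self.wash_times]
        return ids


def umi_capacity(max_clusters: float, redundancy: int = DEFAULT_REDUNDANCY) -> float:
    """Theoretical maximum number of distinct UMIs a flow cell can carry.

    A flow cell with ``max_clusters`` cluster positions read at
    ``redundancy``-fold UMI replication can resolve at most
    ``max_clusters / redundancy`` clones.
    """
    if max_clusters <= 0 or redundancy < 1:
        raise ValueError("max_clusters must be positive and redundancy >= 1")
    return max_clusters / redundancy


def _random_umis(n: int, rng: np.random.Generator) -> list:
    umis = set()
    out = []
    while len(out) < n:
        umi = "".join(rng.choice(list(DNA), size=UMI_LENGTH))
        if umi not in umis:
            umis.add(umi)
            out.append(umi)
    return out


def make_library(
    n_clones: int,
    kd_range=(1e-10, 1e-6),
    seed: int = 0,
    nonbinder_frac: float = 0.0,
    cdr_length: int = 20,
    kd1_range=(1e-3, 1e-2),
    kd2_range=(1e-5, 1e-4),
    kd_values=None,
) -> pd.DataFrame:
    """Draw a clone truth table.

    Equilibrium constants are log-uniform over ``kd_range``.  A
    ``nonbinder_frac`` fraction of clones is marked as non-binders: their
    display efficiency is set so low that their maximal binding signal sits
    below typical background.  Biphasic dissociation rates are log-uniform
    over their ranges with the fast rate always >= the slow rate.
    """
    if n_clones < 1:
        raise ValueError("n_clones must be >= 1")
    lo, hi = float(kd_range[0]), float(kd_range[1])
    if lo <= 0 or hi <= 0 or hi < lo:
        raise ValueError(f"invalid kd_range {kd_range!r}: need 0 < lo <= hi")
    if not 0.0 <= nonbinder_frac <= 1.0:
        raise ValueError("nonbinder_frac must lie in [0, 1]")

    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    if kd_values is not None:
        kds = np.asarray(kd_values, dtype=float)
        if len(kds) != n_clones or np.any(kds <= 0):
            raise ValueError("kd_values must give one positive K_D per clone")
    elif hi == lo:
        kds = np.full(n_clones, lo)
    else:
        kds = 10 ** rng.uniform(math.log10(lo), math.log10(hi), size=n_clones)
    kd1 = 10 ** rng.uniform(*np.log10(kd1_range), size=n_clones)
    kd2 = 10 ** rng.uniform(*np.log10(kd2_range), size=n_clones)
    fast = np.maximum(kd1, kd2)
    slow = np.minimum(kd1, kd2)
    display_eff = rng.uniform(0.5, 1.0, size=n_clones)
    r1_frac = rng.uniform(0.3, 0.7, size=n_clones)

    n_non = int(round(nonbinder_frac * n_clones))
    is_binder = np.ones(n_clones, dtype=bool)
    if n_non:
        idx = rng.choice(n_clones, size=n_non, replace=False)
        is_binder[idx] = False
        display_eff[idx] = 0.01  # maximal signal ~1% of Fmax, below background

    cdrs = ["".join(rng.choice(list(AA20), size=cdr_length)) for _ in range(n_clones)]
    umis = _random_umis(n_clones, rng)
    return pd.DataFrame(
        {
            "clone_id": [f"clone{i:05d}" for i in range(n_clones)],
            "umi": umis,
            "cdr_seq": cdrs,
            "true_kd": kds,
            "kd1_true": fast,
            "kd2_true": slow,
            "display_eff": display_eff,
            "r1_frac": r1_frac,
            "is_binder": is_binder,
        }
    )


def lay_out_clusters(
    clones: pd.DataFrame,
    redundancy: int = DEFAULT_REDUNDANCY,
    tile_shape=DEFAULT_TILE_SHAPE,
    min_spacing: float = 6.0,
    seed: int = 0,
    margin: int = 8,
    jitter: float = 0.0,
    n_tiles: int = 1,
) -> pd.DataFrame:
    """Place ``redundancy`` clusters per clone with a pairwise spacing floor.

    Placement uses a jittered grid: cells are ``min_spacing + 2*jitter`` apart
    so that any two jittered centres remain at least ``min_spacing`` apart.
    ``jitter=0`` snaps centres to exact grid (integer-friendly) positions.
    Raises when the requested tile(s) cannot host all clusters, naming the
    required area.
    """
    if redundancy < 1:
        raise ValueError("redundancy must be >= 1")
    h, w = int(tile_shape[0]), int(tile_shape[1])
    pitch = float(min_spacing) + 2.0 * float(jitter)
    nx = int((w - 2 * margin) // pitch) + 1
    ny = int((h - 2 * margin) // pitch) + 1
    capacity = nx * ny * n_tiles
    n_points = len(clones) * redundancy
    if n_points > capacity:
        need = n_points * pitch * pitch
        raise ValueError(
            f"cannot place {n_points} clusters at spacing {min_spacing} px on "
            f"{n_tiles} tile(s) of {h}x{w}; roughly {need:.0f} px^2 required"
        )
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(2)[1])
    # all grid sites across tiles, shuffled once
    sites = np.array(
        [(t, margin + i * pitch, margin + j * pitch)
         for t in range(n_tiles) for j in range(ny) for i in range(nx)]
    )
    order = rng.permutation(len(sites))
    chosen = sites[order[:n_points]]
    if jitter > 0:
        chosen = chosen.astype(float)
        chosen[:, 1:] += rng.uniform(-jitter, jitter, size=(n_points, 2))

    rows = []
    k = 0
    for _, clone in clones.iterrows():
        for _ in range(redundancy):
            t, x, y = chosen[k]
            rows.append((clone["umi"], int(t), float(x), float(y), clone["clone_id"]))
            k += 1
    return pd.DataFrame(rows, columns=["umi", "tile", "x", "y", "clone_id"])


def equilibrium_signal(clone, conc, fmax: float = DEFAULT_FMAX, fmin: float = DEFAULT_FMIN):
    """Forward equilibrium-binding signal R = A/(1 + K_D/x) + Fmin.

    The clone's saturating amplitude is ``display_eff * fmax``.  ``conc`` may
    be a scalar or array of molar concentrations; conc = 0 returns ``fmin``.
    """
    conc = np.asarray(conc, dtype=float)
    if np.any(conc < 0):
        raise ValueError("concentration must be non-negative")
    amp = float(clone["display_eff"]) * fmax
    kd = float(clone["true_kd"])
    with np.errstate(divide="ignore"):
        frac = np.where(conc > 0, 1.0 / (1.0 + kd / np.where(conc > 0, conc, 1.0)), 0.0)
    out = fmin + amp * frac
    return float(out) if out.ndim == 0 else out


def dissociation_signal(clone, t, t0: float = 0.0, r0: float = DEFAULT_FMAX):
    """Biphasic decay R(t) = R1 e^(-kd1 (t-t0)) + (R0-R1) e^(-kd2 (t-t0))."""
    t = np.asarray(t, dtype=float)
    if np.any(t < t0):
        raise ValueError("t must be >= t0")
    r1 = float(clone["r1_frac"]) * r0
    kd1 = float(clone["kd1_true"])
    kd2 = float(clone["kd2_true"])
    dt = t - t0
    out = r1 * np.exp(-kd1 * dt) + (r0 - r1) * np.exp(-kd2 * dt)
    return float(out) if out.ndim == 0 else out


def polynomial_gain_field(tile_shape=DEFAULT_TILE_SHAPE, lo: float = 0.7,
                          hi: float = 1.3, seed: int = 0) -> np.ndarray:
    """Smooth low-order 2D polynomial gain in [lo, hi] emulating vignetting."""
    h, w = tile_shape
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(3)[2])
    yy, xx = np.mgrid[0:h, 0:w]
    u = (xx - w / 2) / (w / 2)
    v = (yy - h / 2) / (h / 2)
    c = rng.uniform(-1, 1, size=6)
    raw = c[0] + c[1] * u + c[2] * v + c[3] * u * v + c[4] * u ** 2 + c[5] * v ** 2
    rmin, rmax = raw.min(), raw.max()
    if rmax - rmin < 1e-12:
        return np.full((h, w), (lo + hi) / 2)
    return lo + (hi - lo) * (raw - rmin) / (rmax - rmin)


def render_tile(
    clusters: pd.DataFrame,
    values,
    tile_shape=DEFAULT_TILE_SHAPE,
    psf_sigma: float = DEFAULT_PSF_SIGMA,
    illumination=None,
    background: float = DEFAULT_BACKGROUND,
    noise_sd: float = 0.0,
    stage_offset=(0.0, 0.0),
    seed: int = 0,
) -> np.ndarray:
    """Render one tile image: Gaussian spots + gain field + additive noise.

    Each cluster is an amplitude-scaled 2D Gaussian at (x+dx, y+dy); the
    multiplicative illumination field applies to background and signal alike,
    then zero-mean Gaussian noise of sd ``noise_sd`` is added and the result
    is clipped to the 16-bit range.
    """
    if psf_sigma <= 0:
        raise ValueError("psf_sigma must be positive")
    h, w = int(tile_shape[0]), int(tile_shape[1])
    img = np.zeros((h, w), dtype=np.float64)
    values = np.asarray(values, dtype=float)
    dx, dy = float(stage_offset[0]), float(stage_offset[1])
    half = max(3, int(math.ceil(4 * psf_sigma)))
    for (x, y), v in zip(clusters[["x", "y"]].to_numpy(dtype=float), values):
        cx, cy = x + dx, y + dy
        x0, x1 = int(math.floor(cx)) - half, int(math.floor(cx)) + half + 1
        y0, y1 = int(math.floor(cy)) - half, int(math.floor(cy)) + half + 1
        xs = np.arange(max(x0, 0), min(x1, w))
        ys = np.arange(max(y0, 0), min(y1, h))
        if len(xs) == 0 or len(ys) == 0:
            continue
        gx = np.exp(-((xs - cx) ** 2) / (2 * psf_sigma ** 2))
        gy = np.exp(-((ys - cy) ** 2) / (2 * psf_sigma ** 2))
        img[np.ix_(ys, xs)] += v * np.outer(gy, gx)

    img += background
    if illumination is not None:
        gain = np.asarray(illumination, dtype=float)
        if gain.shape != (h, w):
            raise ValueError("illumination field shape must match tile shape")
        img *= gain
    if noise_sd > 0:
        rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(4)[3])
        img += rng.normal(0.0, noise_sd, size=img.shape)
    return np.clip(np.rint(img), 0, 65535).astype(np.uint16)


def simulate_reads(
    clones: pd.DataFrame,
    reads_per_umi: int = 3,
    sub_rate: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Emit ``reads_per_umi`` CDR reads per UMI with i.i.d. substitutions."""
    if reads_per_umi < 1:
        raise ValueError("reads_per_umi must be >= 1")
    if not 0.0 <= sub_rate < 1.0:
        raise ValueError("sub_rate must lie in [0, 1)")
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(5)[4])
    alphabet = np.array(list(AA20))
    rows = []
    for _, clone in clones.iterrows():
        base = np.array(list(clone["cdr_seq"]))
        for _ in range(reads_per_umi):
            read = base.copy()
            if sub_rate > 0:
                hit = rng.random(len(read)) < sub_rate
                if hit.any():
                    for i in np.flatnonzero(hit):
                        choices = alphabet[alphabet != read[i]]
                        read[i] = rng.choice(choices)
            rows.append((clone["umi"], "".join(read)))
    return pd.DataFrame(rows, columns=["umi", "read_seq"])


def simulate_experiment(
    outdir: str,
    n_clones: int = 50,
    schedule: AssaySchedule | None = None,
    seed: int = 0,
    redundancy: int = DEFAULT_REDUNDANCY,
    tile_shape=DEFAULT_TILE_SHAPE,
    min_spacing: float = 6.0,
    jitter: float = 0.0,
    kd_range=(1e-10, 1e-6),
    kd_values=None,
    nonbinder_frac: float = 0.3,
    fmax: float = DEFAULT_FMAX,
    fmin: float = DEFAULT_FMIN,
    norm_value: float = 800.0,
    background: float = DEFAULT_BACKGROUND,
    noise_sd: float = 0.0,
    psf_sigma: float = DEFAULT_PSF_SIGMA,
    uniform_illumination: bool = True,
    max_stage_offset: int = 0,
    reads_per_umi: int = 3,
    sub_rate: float = 0.0,
) -> dict:
    """Write a complete synthetic experiment to ``outdir`` and return a manifest.

    Produces ``images/<condition>_<channel>_tile<k>.tif`` for every condition
    in the schedule (equilibrium points then wash points), plus
    ``clusters.csv``, ``reads.csv``, ``truth.csv`` and ``manifest.json``.
    """
    schedule = schedule or AssaySchedule()
    os.makedirs(os.path.join(outdir, "images"), exist_ok=True)
    clones = make_library(n_clones, kd_range=kd_range, seed=seed,
                          nonbinder_frac=nonbinder_frac, kd_values=kd_values)
    clusters = lay_out_clusters(clones, redundancy=redundancy,
                                tile_shape=tile_shape,
                                min_spacing=min_spacing, seed=seed,
                                jitter=jitter)
    by_clone = {cid: clone for cid, clone in clones.set_index("clone_id").iterrows()}

    illum = None
    if not uniform_illumination:
        illum = polynomial_gain_field(tile_shape, seed=seed)

    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(6)[5])
    conditions = {}
    top_conc = schedule.concentrations[-1]
    for cond_i, cond in enumerate(schedule.condition_ids()):
        is_wash = cond.startswith("wash_")
        offset = (0, 0)
        if max_stage_offset > 0:
            offset = tuple(rng.integers(-max_stage_offset, max_stage_offset + 1, size=2))
        paths = []
        for tile in sorted(clusters["tile"].unique()):
            sub = clusters[clusters["tile"] == tile]
            # binding channel: forward model per clone
            vals = np.empty(len(sub))
            for i, cid in enumerate(sub["clone_id"]):
                clone = by_clone[cid]
                if is_wash:
                    t = float(cond[len("wash_"):-1])
                    r0 = equilibrium_signal(clone, top_conc, fmax, fmin) - fmin
                    vals[i] = dissociation_signal(clone, t, 0.0, r0)
                else:
                    c = schedule.concentrations[cond_i]
                    vals[i] = equilibrium_signal(clone, c, fmax, fmin) - fmin
            for channel, v in (
                (schedule.binding_channel, vals),
                (schedule.normalization_channel, np.full(len(sub), norm_value)),
            ):
                img = render_tile(sub, v, tile_shape=tile_shape,
                                  psf_sigma=psf_sigma, illumination=illum,
                                  background=background, noise_sd=noise_sd,
                                  stage_offset=offset,
                                  seed=seed * 1000 + cond_i * 10 + int(tile))
                path = os.path.join(outdir, "images",
                                    f"{cond}_{channel}_tile{tile}.tif")
                tifffile.imwrite(path, img)
                paths.append(path)
        conditions[cond] = {"stage_offset": [int(offset[0]), int(offset[1])],
                            "images": paths}

    reads = simulate_reads(clones, reads_per_umi=reads_per_umi,
                           sub_rate=sub_rate, seed=seed)
    clusters.to_csv(os.path.join(outdir, "clusters.csv"), index=False)
    reads.to_csv(os.path.join(outdir, "reads.csv"), index=False)
    clones.to_csv(os.path.join(outdir, "truth.csv"), index=False)
    manifest = {
        "seed": seed,
        "n_clones": n_clones,
        "redundancy": redundancy,
        "tile_shape": list(tile_shape),
        "schedule": {
            "concentrations": list(schedule.concentrations),
            "wash_times": list(schedule.wash_times),
            "binding_channel": schedule.binding_channel,
            "normalization_channel": schedule.normalization_channel,
        },
        "render": {"fmax": fmax, "fmin": fmin, "background": background,
                   "noise_sd": noise_sd, "psf_sigma": psf_sigma,
                   "norm_value": norm_value,
                   "uniform_illumination": uniform_illumination},
        "conditions": conditions,
    }
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
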