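"""Synthetic free-end point clouds and point-cloud I/O.

The generator draws i.i.d. samples from the normalized scenario densities by
rejection sampling from a uniform envelope over the bounding box.  The
clouds emulate the coarse-grained-simulation point clouds the model was
built to describe; they are i.i.d. by construction (no temporal
correlation), which is what every distributional use downstream assumes.

A minimal reader for oxDNA-style configuration/topology text files is
included for ingesting real trajectory positions (0.8518 nm per oxDNA
length unit).
"""

from __future__ import annotations

import json
import math
import pathlib
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .geometry import bounding_box, density_xyz, marginal_density, _gauss_nodes
from .params import ConfinementParams

__all__ = [
    "PointCloud",
    "sample_free_end",
    "ks_marginal_check",
    "write_point_cloud",
    "read_point_cloud",
    "read_oxdna_positions",
    "OXDNA_LENGTH_NM",
]

#: Standard oxDNA length unit in nm.
OXDNA_LENGTH_NM = 0.8518


class EnvelopeError(RuntimeError):
    """Rejection-sampling envelope failure (acceptance rate too low)."""


class PointCloudFormatError(ValueError):
    """Malformed point-cloud or trajectory file."""


@dataclass
class PointCloud:
    """Free-end positions (nm) with provenance.

    ``source`` is ``"synthetic"`` for sampled clouds (then ``params`` and
    ``seed`` identify the draw) or ``"trajectory-file"`` for ingested
    trajectory positions.
    """

    positions: np.ndarray
    scenario: str
    params: ConfinementParams | None = None
    seed: int | None = None
    source: str = "synthetic"
    acceptance_rate: float | None = None

    def __len__(self) -> int:
        return len(self.positions)


def sample_free_end(scenario: str, params: ConfinementParams, n: int,
                    seed: int, batch: int = 200_000,
                    envelope_safety: float = 1.2) -> PointCloud:
    """Draw ``n`` i.i.d. free-end positions from the scenario density.

    Rejection sampling from a uniform envelope over the bounding box; the
    envelope constant is the density maximum on a coarse grid times a
    safety factor.  Identical ``(scenario, params, n, seed)`` give bitwise
    identical clouds.  Raises :class:`EnvelopeError` if the acceptance rate
    drops below 1e-4.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    params.require_for(scenario)
    box = bounding_box(scenario, params)
    # envelope constant from a coarse grid scan
    axes = [np.linspace(lo, hi, 64) for lo, hi in box]
    dmax = float(
        density_xyz(scenario, axes[0][:, None, None], axes[1][None, :, None],
                    axes[2][None, None, :], params).max()
    )
    if dmax <= 0:
        raise EnvelopeError("density is zero on the bounding box")
    ceiling = envelope_safety * dmax
    rng = np.random.default_rng(seed)
    lo = np.array([b[0] for b in box])
    span = np.array([b[1] - b[0] for b in box])
    accepted: list[np.ndarray] = []
    n_drawn = n_kept = 0
    while n_kept < n:
        pts = lo + span * rng.random((batch, 3))
        dens = density_xyz(scenario, pts[:, 0], pts[:, 1], pts[:, 2], params)
        keep = rng.random(batch) * ceiling < dens
        n_drawn += batch
        sel = pts[keep]
        accepted.append(sel)
        n_kept += len(sel)
        if n_drawn >= 10 * batch and n_kept / n_drawn < 1e-4:
            raise EnvelopeError(
                f"acceptance rate {n_kept / n_drawn:.2e} below 1e-4"
            )
    positions = np.concatenate(accepted)[:n]
    return PointCloud(positions=positions, scenario=scenario, params=params,
                      seed=seed, source="synthetic",
                      acceptance_rate=n_kept / n_drawn)


def ks_marginal_check(cloud: PointCloud, scenario: str,
                      params: ConfinementParams,
                      n_grid: int = 2001) -> dict[str, tuple[float, int]]:
    """One-sample Kolmogorov-Smirnov distances between the cloud's empirical
    marginals and the model marginal CDFs, per axis.

    Returns ``{axis: (ks_distance, n)}``.  Requires at least 1000 points so
    the asymptotic KS band is meaningful.
    """
    n = len(cloud)
    if n < 1000:
        raise ValueError(f"need at least 1000 points, got {n}")
    box = bounding_box(scenario, params)
    out = {}
    for i, axis in enumerate("xyz"):
        grid = np.linspace(box[i][0], box[i][1], n_grid)
        pdf = marginal_density(scenario, axis, params, grid)
        cdf_vals = np.concatenate([[0.0], np.cumsum(
            0.5 * (pdf[1:] + pdf[:-1]) * np.diff(grid))])
        cdf_vals /= cdf_vals[-1]
        samples = np.sort(cloud.positions[:, i])
        f = np.interp(samples, grid, cdf_vals, left=0.0, right=1.0)
        k = np.arange(1, n + 1)
        d = max(float(np.max(k / n - f)), float(np.max(f - (k - 1) / n)))
        out[axis] = (d, n)
    return out


# -- point-cloud CSV -----------------------------------------------------------

def write_point_cloud(cloud: PointCloud, path: str | pathlib.Path) -> None:
    """Write a cloud as x,y,z CSV with a commented JSON metadata header."""
    meta = {
        "scenario": cloud.scenario,
        "source": cloud.source,
        "seed": cloud.seed,
        "params": cloud.params.to_dict() if cloud.params is not None else None,
    }
    lines = ["# point-cloud " + json.dumps(meta, sort_keys=True), "x,y,z"]
    for p in cloud.positions:
        lines.append(f"{float(p[0])!r},{float(p[1])!r},{float(p[2])!r}")
    pathlib.Path(path).write_text("\n".join(lines) + "\n")


def read_point_cloud(path: str | pathlib.Path) -> PointCloud:
    """Read a cloud written by :func:`write_point_cloud`.

    Malformed rows raise :class:`PointCloudFormatError` naming the line.
    """
    meta: dict = {}
    rows = []
    header_seen = False
    for lineno, ln in enumerate(pathlib.Path(path).read_text().splitlines(), 1):
        if ln.startswith("# point-cloud "):
            meta = json.loads(ln[len("# point-cloud "):])
            continue
        if ln.startswith("#") or not ln.strip():
            continue
        if not header_seen:
            if ln.strip() != "x,y,z":
                raise PointCloudFormatError(
                    f"{path}:{lineno}: expected header 'x,y,z', got {ln!r}"
                )
            header_seen = True
            continue
        parts = ln.split(",")
        if len(parts) != 3:
            raise PointCloudFormatError(
                f"{path}:{lineno}: expected 3 fields, got {len(parts)}"
            )
        try:
            vals = [float(v) for v in parts]
        except ValueError as exc:
            raise PointCloudFormatError(f"{path}:{lineno}: {exc}") from None
        for fieldname, v in zip("xyz", vals):
            if not math.isfinite(v):
                raise PointCloudFormatError(
                    f"{path}:{lineno}: non-finite {fieldname} coordinate"
                )
        rows.append(vals)
    if not header_seen:
        raise PointCloudFormatError(f"{path}: missing 'x,y,z' header")
    if not rows:
        raise PointCloudFormatError(f"{path}: no data rows (empty cloud)")
    params = None
    if meta.get("params"):
        params = ConfinementParams.from_dict(meta["params"])
    return PointCloud(positions=np.array(rows), scenario=meta.get("scenario", ""),
                      params=params, seed=meta.get("seed"),
                      source=meta.get("source", "synthetic"))


# -- oxDNA configuration/topology reader ---------------------------------------

def read_oxdna_positions(conf_path: str | pathlib.Path,
                         topology_path: str | pathlib.Path,
                         nucleotide_index: int,
                         tether_index: int = 0) -> PointCloud:
    """Extract one nucleotide's position series from an oxDNA trajectory.

    Reads the standard oxDNA configuration text layout (per-frame ``t``,
    ``b``, ``E`` headers followed by one 15-column line per nucleotide) and
    the matching topology file (for the nucleotide count), converts lengths
    to nm (0.8518 nm per oxDNA unit) and translates every frame so the
    tether nucleotide sits at the origin.
    """
    top_lines = pathlib.Path(topology_path).read_text().splitlines()
    if not top_lines:
        raise PointCloudFormatError(f"{topology_path}: empty topology")
    try:
        n_nuc = int(top_lines[0].split()[0])
    except (IndexError, ValueError):
        raise PointCloudFormatError(
            f"{topology_path}:1: malformed topology header"
        ) from None
    for name, idx in (("nucleotide_index", nucleotide_index),
                      ("tether_index", tether_index)):
        if not (0 <= idx < n_nuc):
            raise IndexError(f"{name} {idx} out of range [0, {n_nuc})")

    lines = pathlib.Path(conf_path).read_text().splitlines()
    positions = []
    i = 0
    frame = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        frame += 1
        header = lines[i:i + 3]
        if len(header) < 3 or not (header[0].startswith("t")
                                   and header[1].startswith("b")
                                   and header[2].startswith("E")):
            raise PointCloudFormatError(
                f"{conf_path}: malformed timestep header at frame {frame}"
            )
        body = lines[i + 3:i + 3 + n_nuc]
        if len(body) < n_nuc:
            raise PointCloudFormatError(
                f"{conf_path}: truncated frame {frame} "
                f"({len(body)}/{n_nuc} nucleotide lines)"
            )
        def pos(row: str, which: int) -> np.ndarray:
            fields = row.split()
            if len(fields) < 3:
                raise PointCloudFormatError(
                    f"{conf_path}: malformed nucleotide line {which} "
                    f"in frame {frame}"
                )
            return np.array([float(v) for v in fields[:3]])
        p = pos(body[nucleotide_index], nucleotide_index)
        t = pos(body[tether_index], tether_index)
        positions.append((p - t) * OXDNA_LENGTH_NM)
        i += 3 + n_nuc
    if not positions:
        raise PointCloudFormatError(f"{conf_path}: no frames found")
    return PointCloud(positions=np.array(positions), scenario="",
                      params=None, seed=None, source="trajectory-file")
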