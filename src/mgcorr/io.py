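"""Delimited-text readers/writers, JSON result serialization, and test fixtures.

Sample files are plain delimited numeric text with one observation per row:
comma-separated by default, tab-separated when the extension is ``.tsv``.
An optional single header line of non-numeric column names is skipped
automatically.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np

from .statistic import MgcResult

__all__ = [
    "read_samples",
    "write_samples",
    "write_result",
    "result_to_dict",
    "write_map",
    "make_fixture",
    "plot_mgc_map",
]

FIXTURE_KINDS = ("linear_exact", "spiral", "independent", "tiny_random")


def _delimiter_for(path, delimiter=None) -> str:
    if delimiter is not None:
        return delimiter
    return "\t" if str(path).lower().endswith(".tsv") else ","


def read_samples(path, delimiter: str | None = None) -> np.ndarray:
    """Read an ``(n, d)`` sample matrix from delimited numeric text.

    Raises a descriptive ``ValueError`` (naming the 1-based row and column)
    for ragged rows or non-numeric cells, and for empty files.
    """
    path = Path(path)
    delim = _delimiter_for(path, delimiter)
    rows = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter=delim)
        raw = [row for row in reader if any(cell.strip() for cell in row)]
    if not raw:
        raise ValueError(f"{path}: empty file, no samples to read")
    start = 0
    try:
        [float(c) for c in raw[0]]
    except ValueError:
        start = 1  # header line
        if len(raw) == 1:
            raise ValueError(f"{path}: only a header line, no samples to read")
    width = len(raw[start])
    for i, row in enumerate(raw[start:], start=start + 1):
        if len(row) != width:
            raise ValueError(f"{path}: ragged row {i} has {len(row)} cells, expected {width}")
        vals = []
        for j, cell in enumerate(row, start=1):
            try:
                v = float(cell)
            except ValueError:
                raise ValueError(f"{path}: non-numeric cell at row {i}, column {j}: {cell!r}") from None
            if not np.isfinite(v):
                raise ValueError(f"{path}: non-finite value at row {i}, column {j}: {cell!r}")
            vals.append(v)
        rows.append(vals)
    return np.asarray(rows, dtype=float)


def write_samples(X, path, delimiter: str | None = None) -> None:
    """Write a sample matrix as delimited text, full float precision."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    delim = _delimiter_for(path, delimiter)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delim)
        for row in X:
            writer.writerow([repr(float(v)) for v in row])


def result_to_dict(result: MgcResult) -> dict:
    return {
        "statistic": result.statistic,
        "p_value": result.p_value,
        "optimal_scales": [list(s) for s in result.optimal_scales],
        "optimal_scale": list(result.optimal_scale),
        "tau": result.region.tau,
        "region_size": result.region.size,
        "n_permutations": result.n_permutations,
        "seed": result.seed,
        "config": result.config,
        "n": int(result.map.shape[0]),
    }


def write_result(result: MgcResult, path) -> None:
    """Serialize an MgcResult to JSON (scales 1-based, full float precision)."""
    with open(path, "w") as fh:
        json.dump(result_to_dict(result), fh, indent=2)
        fh.write("\n")


def write_map(C, path) -> None:
    """Export a local-correlation map as TSV, rows/columns = scales 1..n."""
    np.savetxt(path, np.asarray(C), delimiter="\t", fmt="%.17g")


def plot_mgc_map(C, path=None, ax=None):
    """Render the MGC-Map as a heat map (decorative helper).

    Scales are 1-based on both axes; a diverging palette is centered at 0 so
    negative local correlations are visually distinct.
    """
    import matplotlib

    if path is not None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    C = np.asarray(C)
    n = C.shape[0]
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    vmax = max(abs(C).max(), 1e-3)
    im = ax.imshow(C.T, origin="lower", extent=(0.5, n + 0.5, 0.5, n + 0.5),
                   cmap="RdBu_r", vmin=-vmax, vmax=vmax, aspect="auto")
    ax.set_xlabel("neighborhood size k (X)")
    ax.set_ylabel("neighborhood size l (Y)")
    ax.figure.colorbar(im, ax=ax, label="local correlation")
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def make_fixture(kind: str, seed: int, out_dir=".", prefix: str | None = None):
    """Write a seeded CSV pair (X, Y) used by tests and examples.

    Kinds: ``linear_exact`` (noiseless affine pair, n=20), ``spiral``
    (1-D spiral, n=60), ``independent`` (multimodal independence, n=100),
    ``tiny_random`` (n=10 unrelated Gaussians for oracle tests).
    """
    from .simulations import SimulationSpec, sample_relationship

    if kind not in FIXTURE_KINDS:
        raise ValueError(f"unknown fixture kind {kind!r}; choose from {FIXTURE_KINDS}")
    rng = np.random.default_rng(seed)
    if kind == "linear_exact":
        X = rng.uniform(-1, 1, (20, 1))
        Y = 2 * X + 3
    elif kind == "spiral":
        pair = sample_relationship(SimulationSpec(type_id=8, n=60, p=1, kappa=1), rng)
        X, Y = pair.X, pair.Y
    elif kind == "independent":
        pair = sample_relationship(SimulationSpec(type_id=20, n=100, p=1), rng)
        X, Y = pair.X, pair.Y
    else:  # tiny_random
        X = rng.standard_normal((10, 2))
        Y = rng.standard_normal((10, 1))
    prefix = prefix or kind
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    x_path = out_dir / f"{prefix}_x.csv"
    y_path = out_dir / f"{prefix}_y.csv"
    write_samples(X, x_path)
    write_samples(Y, y_path)
    return x_path, y_path
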