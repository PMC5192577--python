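"""Genomic contact-probability maps from conformational ensembles.

A contact map is a symmetric matrix P(i, j) of the probability that
genomic bins i and j are in spatial contact, at a fixed bin size
(2.5 kb by default, one lattice bond).  Maps are computed from simulated
ensembles with a proximity-threshold contact criterion: two bins are in
contact in a conformation if any bead pair between them lies within the
capture radius (default sqrt(2) a, the bonded-neighbor scale of the
lattice).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .lattice import Ensemble

__all__ = ["ContactMap", "contact_map_from_ensemble", "read_map", "write_map", "rebin"]


@dataclass
class ContactMap:
    """Symmetric genomic contact-probability matrix.

    Bins are 0-based, half-open genomic intervals of ``bin_size`` bp
    starting at ``start``.  Masked entries are NaN; the diagonal is 1 by
    construction before masking.
    """

    matrix: np.ndarray
    bin_size: int = 2500
    start: int = 0

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError(f"contact map must be square, got shape {m.shape}")
        finite = np.isfinite(m)
        if not np.allclose(
            np.where(finite, m, 0.0), np.where(finite.T, m.T, 0.0), atol=1e-12
        ):
            raise ValueError("contact map must be symmetric (within 1e-12)")
        vals = m[finite]
        if vals.size and (vals.min() < -1e-12 or vals.max() > 1.0 + 1e-12):
            raise ValueError("contact probabilities must lie in [0, 1]")
        self.matrix = m

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[0]

    def bin_of(self, coord_bp: float) -> int:
        return int((coord_bp - self.start) // self.bin_size)

    def coord_of(self, bin_index: int) -> float:
        """Midpoint genomic coordinate [bp] of a bin."""
        return self.start + (bin_index + 0.5) * self.bin_size


def contact_map_from_ensemble(
    ensemble: Ensemble,
    capture_radius: float | None = None,
    bin_size: int | None = None,
    start: int = 0,
) -> ContactMap:
    """Ensemble contact probabilities by proximity thresholding.

    P(i, j) is the fraction of conformations in which any bead of bin i is
    within ``capture_radius`` [nm] of any bead of bin j.  Conformations may
    differ in bead count (loop-length variants); each pair is averaged over
    the conformations that contain both bins.
    """
    if ensemble.n == 0:
        raise ValueError("empty ensemble")
    spec = ensemble.chain_template.spec
    # default: the maximal bonded-neighbor distance sqrt(3) a, so that
    # chain neighbors are in contact by construction
    capture = capture_radius if capture_radius is not None else math.sqrt(3.0) * spec.a
    bin_size = bin_size if bin_size is not None else spec.bp_per_bond
    if bin_size % spec.bp_per_bond != 0:
        raise ValueError(
            f"bin_size {bin_size} is not a multiple of {spec.bp_per_bond} bp per bond"
        )
    beads_per_bin = bin_size // spec.bp_per_bond
    n_bins_max = max(
        int(np.ceil(s.shape[0] / beads_per_bin)) for s in ensemble.conformations
    )
    contact_sum = np.zeros((n_bins_max, n_bins_max))
    counts = np.zeros((n_bins_max, n_bins_max))
    eps = 1e-9
    for sites in ensemble.conformations:
        pos = sites.astype(float) * spec.a
        n_beads = pos.shape[0]
        n_bins = int(np.ceil(n_beads / beads_per_bin))
        close = cdist(pos, pos) <= capture + eps
        if beads_per_bin == 1:
            bin_contact = close
        else:
            bin_contact = np.zeros((n_bins, n_bins), dtype=bool)
            for i in range(n_bins):
                si = slice(i * beads_per_bin, min((i + 1) * beads_per_bin, n_beads))
                for j in range(i, n_bins):
                    sj = slice(j * beads_per_bin, min((j + 1) * beads_per_bin, n_beads))
                    hit = close[si, sj].any()
                    bin_contact[i, j] = bin_contact[j, i] = hit
        contact_sum[:n_bins, :n_bins] += bin_contact
        counts[:n_bins, :n_bins] += 1.0
    with np.errstate(invalid="ignore"):
        P = contact_sum / counts
    P[counts == 0] = np.nan
    return ContactMap(P, bin_size=bin_size, start=start)


def write_map(cmap: ContactMap, path) -> None:
    """Write a map as a dense whitespace matrix with a one-line header.

    Header: ``# bin_size=<bp> start=<bp> n=<bins>`` — bins are 0-based,
    half-open genomic intervals.
    """
    with open(path, "w") as fh:
        fh.write(f"# bin_size={cmap.bin_size} start={cmap.start} n={cmap.n_bins}\n")
        np.savetxt(fh, cmap.matrix, fmt="%.17g")


def read_map(path, symmetrize: bool = False, atol: float = 1e-8) -> ContactMap:
    """Read a dense text matrix (or HDF5 dataset ``map``) written by
    :func:`write_map`.

    Asymmetric input is rejected unless ``symmetrize`` is set, in which
    case (M + M.T)/2 is used.
    """
    path = str(path)
    if path.endswith((".h5", ".hdf5")):
        import h5py

        with h5py.File(path, "r") as fh:
            matrix = fh["map"][...]
            bin_size = int(fh["map"].attrs.get("bin_size", 2500))
            start = int(fh["map"].attrs.get("start", 0))
    else:
        bin_size, start = 2500, 0
        with open(path) as fh:
            first = fh.readline()
            if first.startswith("#"):
                fields = dict(
                    kv.split("=") for kv in first.lstrip("#").split() if "=" in kv
                )
                bin_size = int(fields.get("bin_size", bin_size))
                start = int(fields.get("start", start))
                matrix = np.loadtxt(fh, ndmin=2)
            else:
                matrix = np.loadtxt(path, ndmin=2)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError(f"contact map must be square, got {matrix.shape}")
    finite = np.isfinite(matrix) & np.isfinite(matrix.T)
    asym = np.nanmax(np.abs(np.where(finite, matrix - matrix.T, 0.0))) if matrix.size else 0.0
    if asym > atol:
        if not symmetrize:
            raise ValueError(
                f"asymmetric map (max |M - M.T| = {asym:.3g}); pass symmetrize=True"
            )
        matrix = (matrix + matrix.T) / 2.0
    return ContactMap(matrix, bin_size=bin_size, start=start)


def write_map_hdf5(cmap: ContactMap, path) -> None:
    import h5py

    with h5py.File(path, "w") as fh:
        ds = fh.create_dataset("map", data=cmap.matrix, compression="gzip")
        ds.attrs["bin_size"] = cmap.bin_size
        ds.attrs["start"] = cmap.start


def rebin(cmap: ContactMap, new_bin_size: int) -> ContactMap:
    """Rebin by block-mean downsampling or bilinear upsampling.

    Downsampling requires the new bin size to be a multiple of the old (and
    to divide the matrix evenly); upsampling requires the old to be a
    multiple of the new.  Symmetry is preserved exactly.
    """
    if new_bin_size == cmap.bin_size:
        return ContactMap(cmap.matrix.copy(), bin_size=cmap.bin_size, start=cmap.start)
    n = cmap.n_bins
    if new_bin_size > cmap.bin_size:
        if new_bin_size % cmap.bin_size != 0:
            raise ValueError("new bin size must be a multiple of the old for downsampling")
        k = new_bin_size // cmap.bin_size
        if n % k != 0:
            raise ValueError(f"{n} bins cannot be grouped into blocks of {k}")
        m = cmap.matrix.reshape(n // k, k, n // k, k)
        with np.errstate(invalid="ignore"):
            new = np.nanmean(np.nanmean(m, axis=3), axis=1)
    else:
        if cmap.bin_size % new_bin_size != 0:
            raise ValueError("old bin size must be a multiple of the new for upsampling")
        k = cmap.bin_size // new_bin_size
        # bilinear interpolation on bin midpoints
        from scipy.interpolate import RegularGridInterpolator

        old_mid = np.arange(n) + 0.5
        new_mid = (np.arange(n * k) + 0.5) / k
        new_mid = np.clip(new_mid, old_mid[0], old_mid[-1])
        interp = RegularGridInterpolator(
            (old_mid, old_mid), cmap.matrix, method="linear"
        )
        xx, yy = np.meshgrid(new_mid, new_mid, indexing="ij")
        new = interp(np.stack([xx, yy], axis=-1))
        new = (new + new.T) / 2.0
    return ContactMap(new, bin_size=new_bin_size, start=cmap.start)
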