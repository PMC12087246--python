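"""Reading, validating and writing Hi-C contact maps and interval outputs.

A contact map is a symmetric intra-chromosomal matrix of normalized
interaction frequencies at a fixed bin resolution.  Three on-disk dialects
are accepted and converted to one in-memory representation:

* cooler-layout HDF5 stores (``.cool`` single resolution, ``.mcool``
  multi-resolution under ``resolutions/<res>``),
* a dense whitespace-separated text matrix,
* 3-column sparse text triples ``bin_i  bin_j  value``.

Bins with no usable data (all-missing rows) are flagged missing — stored as
NaN — rather than zero-filled, so that downstream rank comparisons can skip
them instead of being biased by unmappable regions.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ContactMap",
    "read_contact_map",
    "write_contact_map",
    "write_intervals",
    "write_bedgraph",
    "write_domain_table",
]

_DENSE_SYMMETRY_RTOL = 1e-6


@dataclass
class ContactMap:
    """Symmetric normalized intra-chromosomal interaction matrix.

    Parameters
    ----------
    chrom : str
        Chromosome name.
    resolution : int
        Bin width in bp.
    values : ndarray of shape (n_bins, n_bins)
        Symmetric matrix of normalized interaction frequencies; missing
        entries are NaN.
    depth_hint : int or None
        Total valid read pairs of the originating experiment, if known.
        Used only to auto-select the boundary-calling FDR level.
    """

    chrom: str
    resolution: int
    values: np.ndarray
    depth_hint: int | None = None
    missing_bins: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("contact map values must be a square matrix")
        if v.shape[0] == 0:
            raise ValueError("empty (0-bin) contact map")
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        with np.errstate(invalid="ignore"):
            if np.any(v[np.isfinite(v)] < 0):
                raise ValueError("negative interaction frequency")
        finite = np.isfinite(v)
        if not np.array_equal(finite, finite.T) or not np.allclose(
            v[finite & finite.T], v.T[finite & finite.T], rtol=_DENSE_SYMMETRY_RTOL
        ):
            raise ValueError("contact map is not symmetric within tolerance")
        self.values = v
        self.missing_bins = ~finite.any(axis=0)
        # an all-missing row is flagged and fully NaN both ways
        v[self.missing_bins, :] = np.nan
        v[:, self.missing_bins] = np.nan

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]

    def diagonal(self, k: int) -> np.ndarray:
        """Entries m[i, i+k] for i = 0..n-k-1 (NaN where missing)."""
        return np.diagonal(self.values, offset=k).copy()

    def diagonals(self, k_max: int) -> np.ndarray:
        """Padded diagonal array D with D[k, i] = m[i, i+k], NaN beyond range.

        Shape (k_max + 1, n_bins); the layout every scoring kernel consumes.
        """
        n = self.n_bins
        out = np.full((k_max + 1, n), np.nan)
        for k in range(min(k_max, n - 1) + 1):
            out[k, : n - k] = np.diagonal(self.values, offset=k)
        return out


def _read_dense(path: str, chrom: str, resolution: int) -> ContactMap:
    v = np.loadtxt(path, dtype=np.float64, ndmin=2)
    if v.shape[0] != v.shape[1]:
        raise ValueError(f"dense matrix in {path} is not square: {v.shape}")
    finite = np.isfinite(v)
    if not np.allclose(v[finite & finite.T], v.T[finite & finite.T],
                       rtol=_DENSE_SYMMETRY_RTOL):
        raise ValueError(f"dense matrix in {path} is asymmetric beyond tolerance")
    # all-zero rows indicate unmappable bins in dense text dumps
    dead = (np.nan_to_num(v) == 0).all(axis=0)
    v = v.copy()
    v[dead, :] = np.nan
    v[:, dead] = np.nan
    return ContactMap(chrom=chrom, resolution=resolution, values=v)


def _read_sparse(path: str, chrom: str, resolution: int) -> ContactMap:
    n_hint = None
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#") and "n_bins=" in first:
        n_hint = int(first.split("n_bins=")[1].split()[0])
    trip = np.loadtxt(path, dtype=np.float64, ndmin=2)
    if trip.shape[1] != 3:
        raise ValueError(f"sparse triples in {path} must have 3 columns")
    i = trip[:, 0].astype(np.int64)
    j = trip[:, 1].astype(np.int64)
    if np.any(i < 0) or np.any(j < 0):
        raise ValueError("negative bin index in sparse triples")
    n = int(max(i.max(), j.max())) + 1
    if n_hint is not None:
        n = max(n, n_hint)
    v = np.zeros((n, n))
    v[i, j] = trip[:, 2]
    v[j, i] = trip[:, 2]
    dead = (v == 0).all(axis=0)
    v[dead, :] = np.nan
    v[:, dead] = np.nan
    return ContactMap(chrom=chrom, resolution=resolution, values=v)


def _cool_group(h5, resolution: int):
    import h5py  # noqa: F811 (local to keep import cost off the common path)

    if "resolutions" in h5:  # .mcool layout
        key = str(resolution)
        if key not in h5["resolutions"]:
            avail = sorted(int(r) for r in h5["resolutions"])
            raise ValueError(
                f"resolution {resolution} not in store (available: {avail})"
            )
        return h5["resolutions"][key]
    if "pixels" not in h5:
        raise ValueError("not a cooler-layout HDF5 file")
    stored = int(h5.attrs.get("bin-size", resolution))
    if stored != resolution:
        raise ValueError(f"store is at {stored} bp, requested {resolution}")
    return h5


def _read_cool(path: str, chrom: str, resolution: int) -> ContactMap:
    import h5py

    with h5py.File(path, "r") as h5:
        grp = _cool_group(h5, resolution)
        chrom_names = [
            c.decode() if isinstance(c, bytes) else str(c)
            for c in grp["chroms/name"][:]
        ]
        if chrom not in chrom_names:
            raise ValueError(f"chromosome {chrom!r} not in {path}")
        cid = chrom_names.index(chrom)
        bin_chrom = grp["bins/chrom"][:]
        mask = bin_chrom == cid
        offsets = np.flatnonzero(mask)
        lo, hi = int(offsets[0]), int(offsets[-1]) + 1
        n = hi - lo
        b1 = grp["pixels/bin1_id"][:]
        b2 = grp["pixels/bin2_id"][:]
        cnt = grp["pixels/count"][:].astype(np.float64)
        sel = (b1 >= lo) & (b1 < hi) & (b2 >= lo) & (b2 < hi)
        i = b1[sel] - lo
        j = b2[sel] - lo
        val = cnt[sel]
        if "weight" in grp["bins"]:
            w = grp["bins/weight"][lo:hi]
            val = val * w[i] * w[j]
        v = np.zeros((n, n))
        v[i, j] = val
        v[j, i] = val
        if "weight" in grp["bins"]:
            bad = ~np.isfinite(w)
            v[bad, :] = np.nan
            v[:, bad] = np.nan
        dead = (np.nan_to_num(v) == 0).all(axis=0)
        v[dead, :] = np.nan
        v[:, dead] = np.nan
        depth = grp.attrs.get("sum", None)
        return ContactMap(
            chrom=chrom,
            resolution=resolution,
            values=v,
            depth_hint=int(depth) if depth is not None else None,
        )


def read_contact_map(path: str, chrom: str, resolution: int) -> ContactMap:
    """Read a contact map from any accepted dialect.

    The dialect is chosen by extension: ``.cool``/``.mcool`` are HDF5
    cooler-layout stores; anything else is sniffed as sparse triples
    (3 columns) or a dense matrix.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    ext = os.path.splitext(path)[1].lower()
    if ext in (".cool", ".mcool"):
        return _read_cool(path, chrom, resolution)
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith(("#", "track")):
                ncol = len(line.split())
                break
        else:
            raise ValueError(f"{path} contains no data")
    if ncol == 3:
        return _read_sparse(path, chrom, resolution)
    return _read_dense(path, chrom, resolution)


def write_contact_map(cmap: ContactMap, path: str) -> None:
    """Write a contact map; dialect chosen by extension (.cool or text).

    Round-trips: ``read_contact_map(write_contact_map(m))`` equals ``m``
    on non-missing entries and preserves missing flags.
    """
    ext = os.path.splitext(path)[1].lower()
    if ext in (".cool", ".mcool"):
        _write_cool(cmap, path, multires=ext == ".mcool")
    else:
        v = cmap.values
        iu, ju = np.triu_indices(cmap.n_bins)
        keep = np.isfinite(v[iu, ju]) & (v[iu, ju] != 0)
        trip = np.column_stack([iu[keep], ju[keep], v[iu, ju][keep]])
        # sentinel entries pin n_bins for all-trailing-missing maps
        header = f"# chrom={cmap.chrom} resolution={cmap.resolution} n_bins={cmap.n_bins}"
        np.savetxt(path, trip, fmt="%d\t%d\t%.17g", header=header)


def _write_cool(cmap: ContactMap, path: str, multires: bool = False) -> None:
    import h5py

    n = cmap.n_bins
    r = cmap.resolution
    iu, ju = np.triu_indices(n)
    val = cmap.values[iu, ju]
    keep = np.isfinite(val) & (val != 0)
    with h5py.File(path, "w") as h5:
        grp = h5.create_group(f"resolutions/{r}") if multires else h5
        grp.attrs["bin-size"] = r
        grp.attrs["format"] = "HDF5::Cooler"
        if cmap.depth_hint is not None:
            grp.attrs["sum"] = cmap.depth_hint
        grp.create_dataset("chroms/name", data=[cmap.chrom.encode()])
        grp.create_dataset("chroms/length", data=[n * r])
        grp.create_dataset("bins/chrom", data=np.zeros(n, dtype=np.int32))
        grp.create_dataset("bins/start", data=np.arange(n, dtype=np.int64) * r)
        grp.create_dataset("bins/end", data=(np.arange(n, dtype=np.int64) + 1) * r)
        w = np.ones(n)
        w[cmap.missing_bins] = np.nan
        grp.create_dataset("bins/weight", data=w)
        grp.create_dataset("pixels/bin1_id", data=iu[keep].astype(np.int64))
        grp.create_dataset("pixels/bin2_id", data=ju[keep].astype(np.int64))
        grp.create_dataset("pixels/count", data=val[keep])


def write_intervals(records, path: str, fmt: str = "bed") -> None:
    """Write TADs (BED) or a per-bin score track (bedGraph).

    BED convention: 0-based half-open; a TAD whose furthermost inside bins
    are a and b at resolution r spans ``[a*r, (b+1)*r)``.  The name column
    carries the nesting-level tag and the score column the TAD score
    rescaled from [-1, 1] to [0, 1000].
    """
    if fmt == "bed":
        lines = []
        resolutions = set()
        for rec in records:
            chrom, a, b, r = rec.chrom, rec.left_bin, rec.right_bin, rec.resolution
            if b < a:
                raise ValueError(f"TAD with right bin {b} < left bin {a}")
            resolutions.add(r)
            score = int(round((getattr(rec, "score", 0.0) + 1.0) / 2.0 * 1000))
            level = getattr(rec, "level", 0)
            lines.append(
                f"{chrom}\t{a * r}\t{(b + 1) * r}\tlevel_{level}\t{score}\t."
            )
        if len(resolutions) > 1:
            raise ValueError("mixed resolutions in one BED output")
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + ("\n" if lines else ""))
    elif fmt == "bedgraph":
        write_bedgraph(records, path)
    else:
        raise ValueError(f"unknown interval format {fmt!r}")


def write_bedgraph(track, path: str) -> None:
    """Write one per-bin score vector as bedGraph rows (one row per bin)."""
    chrom, r, scores = track.chrom, track.resolution, np.asarray(track.scores)
    with open(path, "w") as fh:
        for i, s in enumerate(scores):
            fh.write(f"{chrom}\t{i * r}\t{(i + 1) * r}\t{s:.6g}\n")


def write_domain_table(tads, path: str) -> None:
    """Tab-separated domain table: chrom, start_bin, end_bin, score, level, parent."""
    with open(path, "w") as fh:
        fh.write("chrom\tstart_bin\tend_bin\tscore\tlevel\tparent\n")
        for idx, t in enumerate(tads):
            parent = t.parent if t.parent is not None else -1
            fh.write(
                f"{t.chrom}\t{t.left_bin}\t{t.right_bin}\t{t.score:.6g}"
                f"\t{t.level}\t{parent}\n"
            )
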