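"""File-backed genotype store and format converters.

Genotype matrices are stored markers-by-samples with additive dosage coding:
0/1/2 copies of the counted (alternate/minor) allele, or fractional dosages
in [0, 2]. The on-disk store is a directory holding a flat binary matrix
(``numpy.memmap``-readable), JSON metadata and a tab-delimited marker map,
so that any single marker row can be read with O(n_samples) resident memory
regardless of total matrix size, and any number of concurrent readers see
identical, immutable data.

Supported input formats: VCF (plain or bgzipped, via cyvcf2), PLINK binary
bed/bim/fam, HapMap text, and delimited numeric dosage matrices.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeStore",
    "StoreWriter",
    "GenotypeIOError",
    "convert",
    "convert_vcf",
    "convert_plink",
    "convert_hapmap",
    "convert_numeric",
    "align_samples",
    "marker_stats",
    "load_phenotype",
]

MISSING_BYTE = 255

_META_FILE = "store.json"
_DOSAGE_FILE = "dosages.bin"
_MARKER_FILE = "markers.tsv"

MARKER_COLUMNS = ["snp_id", "chrom", "pos", "allele_major", "allele_minor", "maf"]

# genotype codes accepted in HapMap sample columns; IUPAC ambiguity letters
# encode heterozygotes, single bases encode homozygotes
_IUPAC = {
    "A": "AA", "C": "CC", "G": "GG", "T": "TT",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
}
_HAPMAP_MISSING = {"NN", "N", "--", "??", "00", "0"}


class GenotypeIOError(ValueError):
    """Raised for malformed or inconsistent genotype inputs."""


class GenotypeStore:
    """Read-only, memory-mapped dosage matrix with marker map and sample IDs.

    Parameters
    ----------
    path
        Directory written by :class:`StoreWriter` (or any converter).

    Notes
    -----
    Hard calls are stored as one byte per genotype with 255 as the missing
    sentinel; fractional dosages use float32 with NaN as the sentinel.
    Reading a row slices the memmap, so peak additional memory for a
    single-row read is O(n_samples).
    """

    def __init__(self, path):
        path = Path(path)
        meta_path = path / _META_FILE
        if not meta_path.exists():
            raise GenotypeIOError(f"not a genotype store (missing {_META_FILE}): {path}")
        meta = json.loads(meta_path.read_text())
        self.path = path
        self.meta = meta
        self.samples: list[str] = list(meta["samples"])
        self.dtype = np.dtype(meta["dtype"])
        self.n_markers = int(meta["n_markers"])
        self.n_samples = int(meta["n_samples"])
        self._dosages = np.memmap(
            path / _DOSAGE_FILE, dtype=self.dtype, mode="r",
            shape=(self.n_markers, self.n_samples),
        )
        self.markers = pd.read_csv(
            path / _MARKER_FILE, sep="\t", dtype={"chrom": str, "snp_id": str}
        )

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_markers, self.n_samples)

    def dosage_row(self, i: int, sample_index=None) -> np.ndarray:
        """One marker's dosages as float64 with NaN for missing."""
        return self.dosage_block(i, i + 1, sample_index)[0]

    def dosage_block(self, start: int, stop: int, sample_index=None) -> np.ndarray:
        """Rows [start, stop) as float64 with NaN for missing entries."""
        raw = np.asarray(self._dosages[start:stop])
        if sample_index is not None:
            raw = raw[:, sample_index]
        out = raw.astype(np.float64)
        if self.dtype == np.uint8:
            out[raw == MISSING_BYTE] = np.nan
        return out

    def imputed_block(self, start: int, stop: int, sample_index=None):
        """Mean-imputed block plus per-marker counted-allele frequency.

        Returns ``(X, p)`` where ``X`` is the (stop-start, n) float matrix
        with missing entries replaced by the per-marker mean dosage and
        ``p = mean/2`` is the frequency of the counted allele (NaN for
        all-missing markers, whose rows are filled with 0).
        """
        X = self.dosage_block(start, stop, sample_index)
        return _impute_block(X)

    def iter_blocks(self, block_size: int = 2048, sample_index=None, imputed: bool = False):
        for start in range(0, self.n_markers, block_size):
            stop = min(start + block_size, self.n_markers)
            if imputed:
                X, p = self.imputed_block(start, stop, sample_index)
                yield start, X, p
            else:
                yield start, self.dosage_block(start, stop, sample_index)


def _impute_block(X: np.ndarray):
    miss = np.isnan(X)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
        mean = np.nanmean(X, axis=1)
    p = mean / 2.0
    fill = np.where(np.isnan(mean), 0.0, mean)
    if miss.any():
        X = np.where(miss, fill[:, None], X)
    return X, p


class StoreWriter:
    """Sequential writer building a :class:`GenotypeStore` directory.

    Append marker blocks (float arrays, NaN = missing) together with their
    marker records; MAF is computed and cached per marker as data streams
    through, so no second pass over the matrix is needed.
    """

    def __init__(self, path, samples: Sequence[str], dtype: str = "uint8"):
        self.path = Path(path)
        self.path.mkdir(parents=True, exist_ok=True)
        self.samples = [str(s) for s in samples]
        if len(set(self.samples)) != len(self.samples):
            raise GenotypeIOError("duplicate sample IDs")
        self.dtype = np.dtype(dtype)
        if self.dtype not in (np.dtype("uint8"), np.dtype("float32")):
            raise GenotypeIOError(f"unsupported store dtype {dtype}")
        self._fh = open(self.path / _DOSAGE_FILE, "wb")
        self._records: list[dict] = []
        self.n_markers = 0

    def append(self, block: np.ndarray, records: Sequence[dict]):
        block = np.atleast_2d(np.asarray(block, dtype=np.float64))
        if block.shape[1] != len(self.samples):
            raise GenotypeIOError(
                f"block has {block.shape[1]} columns, store has {len(self.samples)} samples"
            )
        if len(records) != block.shape[0]:
            raise GenotypeIOError("marker records do not match block rows")
        finite = block[np.isfinite(block)]
        if finite.size and (finite.min() < 0 or finite.max() > 2):
            raise GenotypeIOError("dosages must lie in [0, 2]")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            freq = np.nanmean(block, axis=1) / 2.0
        maf = np.minimum(freq, 1.0 - freq)
        if self.dtype == np.uint8:
            enc = np.where(np.isnan(block), MISSING_BYTE, np.rint(block)).astype(np.uint8)
        else:
            enc = block.astype(np.float32)
        self._fh.write(enc.tobytes())
        for rec, m in zip(records, maf):
            rec = dict(rec)
            rec["maf"] = float(m) if np.isfinite(m) else np.nan
            self._records.append(rec)
        self.n_markers += block.shape[0]

    def finalize(self, extra_meta: Optional[dict] = None) -> GenotypeStore:
        self._fh.close()
        markers = pd.DataFrame(self._records, columns=MARKER_COLUMNS)
        markers.to_csv(self.path / _MARKER_FILE, sep="\t", index=False)
        meta = {
            "n_markers": self.n_markers,
            "n_samples": len(self.samples),
            "dtype": self.dtype.name,
            "samples": self.samples,
        }
        if extra_meta:
            meta.update(extra_meta)
        (self.path / _META_FILE).write_text(json.dumps(meta, indent=1))
        return GenotypeStore(self.path)


# ---------------------------------------------------------------------------
# converters


def convert(source_path, format: str, out_path, **kwargs) -> GenotypeStore:
    """Convert a genotype file to the on-disk store format.

    ``format`` is one of ``vcf``, ``plink_bed``, ``hapmap``, ``numeric``.
    Conversion is deterministic, so re-running with the same inputs yields
    byte-identical dosage content.
    """
    dispatch = {
        "vcf": convert_vcf,
        "plink_bed": convert_plink,
        "hapmap": convert_hapmap,
        "numeric": convert_numeric,
    }
    if format not in dispatch:
        raise GenotypeIOError(f"unknown genotype format: {format!r}")
    return dispatch[format](source_path, out_path, **kwargs)


def convert_vcf(source_path, out_path, block_size: int = 4096) -> GenotypeStore:
    """Biallelic VCF records to 0/1/2 dosages of the ALT allele.

    Multiallelic records are skipped with a warning and counted in the store
    metadata (``skipped_multiallelic``). Half-missing genotypes (``./1``)
    are treated as missing.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(source_path))
    samples = list(vcf.samples)
    if not samples:
        raise GenotypeIOError("VCF has no samples (GT field required)")
    writer = StoreWriter(out_path, samples, dtype="uint8")
    skipped = 0
    buf_rows, buf_recs = [], []
    for var in vcf:
        if len(var.ALT) != 1:
            skipped += 1
            continue
        # sum called alleles; any half-missing call (./1) counts as missing
        alleles = np.array(var.genotypes, dtype=np.int64)[:, :2]
        d = alleles.sum(axis=1).astype(np.float64)
        d[(alleles < 0).any(axis=1)] = np.nan
        buf_rows.append(d)
        buf_recs.append({
            "snp_id": var.ID or f"{var.CHROM}:{var.POS}",
            "chrom": str(var.CHROM),
            "pos": int(var.POS),
            "allele_major": var.REF,
            "allele_minor": var.ALT[0],
        })
        if len(buf_rows) >= block_size:
            writer.append(np.array(buf_rows), buf_recs)
            buf_rows, buf_recs = [], []
    if buf_rows:
        writer.append(np.array(buf_rows), buf_recs)
    if skipped:
        warnings.warn(f"skipped {skipped} multiallelic VCF record(s)")
    return writer.finalize({"skipped_multiallelic": skipped})


# 256 -> 4 genotype lookup for PLINK 2-bit codes (SNP-major):
# 00 = hom A1 (dosage 2 of A1), 01 = missing, 10 = het, 11 = hom A2
_BED_LUT = np.empty((256, 4), dtype=np.float64)
for _byte in range(256):
    for _j in range(4):
        _code = (_byte >> (2 * _j)) & 0b11
        _BED_LUT[_byte, _j] = {0: 2.0, 1: np.nan, 2: 1.0, 3: 0.0}[_code]


def convert_plink(source_path, out_path, block_size: int = 4096) -> GenotypeStore:
    """PLINK bed/bim/fam triple to a dosage store counting the A1 allele.

    ``source_path`` is the shared prefix or any of the three file paths.
    Only SNP-major bed files (magic ``6c 1b 01``) are supported.
    """
    prefix = Path(str(source_path))
    if prefix.suffix in {".bed", ".bim", ".fam"}:
        prefix = prefix.with_suffix("")
    bed, bim, fam = (prefix.with_suffix(s) for s in (".bed", ".bim", ".fam"))
    for f in (bed, bim, fam):
        if not f.exists():
            raise GenotypeIOError(f"missing PLINK file: {f}")
    bim_df = pd.read_csv(
        bim, sep=r"\s+", header=None,
        names=["chrom", "snp_id", "cm", "pos", "a1", "a2"],
        dtype={"chrom": str, "snp_id": str},
    )
    fam_df = pd.read_csv(fam, sep=r"\s+", header=None, usecols=[0, 1],
                         names=["fid", "iid"], dtype=str)
    n = len(fam_df)
    m = len(bim_df)
    raw = np.fromfile(bed, dtype=np.uint8)
    if raw[:3].tobytes() != b"\x6c\x1b\x01":
        raise GenotypeIOError("not a SNP-major PLINK bed file (bad magic bytes)")
    bpm = (n + 3) // 4  # bytes per marker
    if raw.size - 3 != bpm * m:
        raise GenotypeIOError(
            f"bed payload ({raw.size - 3} bytes) inconsistent with "
            f"{m} markers x {n} samples from bim/fam"
        )
    data = raw[3:].reshape(m, bpm)
    writer = StoreWriter(out_path, fam_df["iid"].tolist(), dtype="uint8")
    for start in range(0, m, block_size):
        stop = min(start + block_size, m)
        block = _BED_LUT[data[start:stop]].reshape(stop - start, bpm * 4)[:, :n]
        recs = [
            {"snp_id": r.snp_id, "chrom": r.chrom, "pos": int(r.pos),
             "allele_major": r.a2, "allele_minor": r.a1}
            for r in bim_df.iloc[start:stop].itertuples()
        ]
        writer.append(block, recs)
    return writer.finalize()


def convert_hapmap(source_path, out_path, block_size: int = 4096) -> GenotypeStore:
    """HapMap text (11 metadata columns) to dosages of the second listed allele.

    Genotypes may be two-letter (``AG``) or single-letter IUPAC codes;
    ``NN``/``N``/``--`` are missing. Anything else is an error.
    """
    df = pd.read_csv(source_path, sep="\t", dtype=str)
    cols = list(df.columns)
    expected = ["rs#", "alleles", "chrom", "pos"]
    if len(cols) < 12 or [c.lower() for c in cols[:4]] != expected:
        raise GenotypeIOError(
            "malformed HapMap header: expected 11 metadata columns starting "
            "rs#, alleles, chrom, pos"
        )
    samples = cols[11:]
    writer = StoreWriter(out_path, samples, dtype="uint8")
    gt = df.iloc[:, 11:].to_numpy(dtype=object)
    rows, recs = [], []
    for i in range(len(df)):
        alleles = str(df.iloc[i, 1]).replace("/", "")
        if len(alleles) != 2:
            raise GenotypeIOError(f"cannot parse HapMap alleles field {df.iloc[i, 1]!r}")
        ref, alt = alleles[0].upper(), alleles[1].upper()
        d = np.empty(len(samples))
        for j, tok in enumerate(gt[i]):
            tok = str(tok).strip().upper()
            if tok in _HAPMAP_MISSING:
                d[j] = np.nan
                continue
            if len(tok) == 1:
                tok = _IUPAC.get(tok)
                if tok is None:
                    raise GenotypeIOError(f"unknown HapMap genotype code {gt[i][j]!r}")
            if len(tok) != 2 or any(a not in (ref, alt) for a in tok):
                raise GenotypeIOError(
                    f"genotype {gt[i][j]!r} inconsistent with alleles {ref}/{alt}"
                )
            d[j] = tok.count(alt)
        rows.append(d)
        recs.append({
            "snp_id": str(df.iloc[i, 0]), "chrom": str(df.iloc[i, 2]),
            "pos": int(df.iloc[i, 3]), "allele_major": ref, "allele_minor": alt,
        })
        if len(rows) >= block_size:
            writer.append(np.array(rows), recs)
            rows, recs = [], []
    if rows:
        writer.append(np.array(rows), recs)
    return writer.finalize()


def convert_numeric(source_path, out_path, map_path=None, block_size: int = 4096) -> GenotypeStore:
    """Delimited numeric dosage matrix (markers x samples, sample header row).

    ``map_path`` is a tab/comma-delimited side file whose first three columns
    are SNP ID, chromosome and position; when omitted, markers are named
    ``m0..m{m-1}`` on a single pseudo-chromosome. Integer 0/1/2 matrices are
    stored as one byte per call; fractional dosages as float32.
    """
    mat = pd.read_csv(source_path, sep=None, engine="python")
    samples = [str(c) for c in mat.columns]
    X = mat.to_numpy(dtype=np.float64)
    finite = X[np.isfinite(X)]
    if finite.size and (finite.min() < 0 or finite.max() > 2):
        raise GenotypeIOError("numeric dosages must lie in [0, 2]")
    integral = finite.size == 0 or np.allclose(finite, np.rint(finite))
    if map_path is not None:
        mp = pd.read_csv(map_path, sep=None, engine="python", dtype=str)
        if len(mp) != len(X):
            raise GenotypeIOError("marker map rows do not match matrix rows")
        recs = [
            {"snp_id": r[0], "chrom": r[1], "pos": int(r[2]),
             "allele_major": "A", "allele_minor": "B"}
            for r in mp.itertuples(index=False)
        ]
    else:
        recs = [
            {"snp_id": f"m{i}", "chrom": "1", "pos": i + 1,
             "allele_major": "A", "allele_minor": "B"}
            for i in range(len(X))
        ]
    writer = StoreWriter(out_path, samples, dtype="uint8" if integral else "float32")
    for start in range(0, len(X), block_size):
        stop = min(start + block_size, len(X))
        writer.append(X[start:stop], recs[start:stop])
    return writer.finalize()


# ---------------------------------------------------------------------------
# plumbing


class AlignedData(NamedTuple):
    sample_index: np.ndarray  # column indices into the store, store order
    sample_ids: list[str]
    y: np.ndarray
    covariates: Optional[np.ndarray]
    n_dropped_missing: int


def load_phenotype(path) -> pd.DataFrame:
    """Read a tab/comma-delimited phenotype table (first column = sample ID)."""
    df = pd.read_csv(path, sep=None, engine="python")
    df.iloc[:, 0] = df.iloc[:, 0].astype(str)
    if df.shape[1] < 2:
        raise GenotypeIOError("phenotype table needs a sample-ID column and >=1 trait")
    if df.iloc[:, 0].duplicated().any():
        raise GenotypeIOError("duplicate sample IDs in phenotype table")
    return df


def align_samples(store: GenotypeStore, pheno: pd.DataFrame,
                  covar: Optional[pd.DataFrame] = None,
                  trait: Optional[str] = None) -> AlignedData:
    """Intersect store columns with phenotype (and covariate) rows.

    The returned index preserves store column order; phenotype rows with a
    missing value for the analyzed trait are dropped and counted.
    """
    if pheno.iloc[:, 0].duplicated().any():
        raise GenotypeIOError("duplicate sample IDs in phenotype table")
    trait = trait or pheno.columns[1]
    ph = pheno.set_index(pheno.columns[0])
    ph.index = ph.index.astype(str)
    ids = set(ph.index)
    if covar is not None:
        cv = covar.set_index(covar.columns[0])
        cv.index = cv.index.astype(str)
        ids &= set(cv.index)
    keep = [(i, s) for i, s in enumerate(store.samples) if s in ids]
    n_missing = 0
    rows = []
    for i, s in keep:
        val = ph.loc[s, trait]
        if pd.isna(val):
            n_missing += 1
        else:
            rows.append((i, s, float(val)))
    if not rows:
        raise GenotypeIOError("no overlapping samples with non-missing phenotype")
    idx = np.array([r[0] for r in rows], dtype=np.intp)
    sample_ids = [r[1] for r in rows]
    y = np.array([r[2] for r in rows])
    C = None
    if covar is not None:
        C = cv.loc[sample_ids].to_numpy(dtype=np.float64)
        if np.isnan(C).any():
            keep_mask = ~np.isnan(C).any(axis=1)
            n_missing += int((~keep_mask).sum())
            idx, y, C = idx[keep_mask], y[keep_mask], C[keep_mask]
            sample_ids = [s for s, k in zip(sample_ids, keep_mask) if k]
            if len(y) == 0:
                raise GenotypeIOError("no samples left after dropping missing covariates")
    return AlignedData(idx, sample_ids, y, C, n_missing)


def marker_stats(store: GenotypeStore, sample_index=None,
                 block_size: int = 4096) -> pd.DataFrame:
    """Per-marker MAF, missing rate and monomorphic flag.

    MAF is computed on non-missing dosages only; a marker with zero dosage
    variance (or all entries missing) is flagged monomorphic, and an
    all-missing marker gets NaN MAF.
    """
    mafs, miss, mono = [], [], []
    for start, X in store.iter_blocks(block_size, sample_index):
        nan = np.isnan(X)
        n_obs = X.shape[1] - nan.sum(axis=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            freq = np.nanmean(X, axis=1) / 2.0
            var = np.nanvar(X, axis=1)
        maf = np.minimum(freq, 1 - freq)
        mafs.append(maf)
        miss.append(nan.sum(axis=1) / X.shape[1])
        mono.append((n_obs == 0) | (var == 0))
    return pd.DataFrame({
        "snp_id": store.markers["snp_id"],
        "maf": np.concatenate(mafs),
        "missing_rate": np.concatenate(miss),
        "monomorphic": np.concatenate(mono),
    })
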