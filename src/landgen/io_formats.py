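"""Readers and writers for the pipeline's on-disk formats.

The common in-memory currency is :class:`GenotypeMatrix` — an individuals x
loci matrix of within-individual alternate-allele frequencies ("dosages").
Diploid calls 0/1/2 map to 0, 0.5, 1; missing calls are ``nan``.  Dosage is
kept on the allele-frequency scale rather than as allele counts so the same
container can hold tetraploid dosages (0.25, 0.75) produced by the read
simulator, even though called genotypes are always diploid-coerced.

Rasters use the ESRI ASCII grid convention: row 0 is the northern edge and
values are registered to cell centers.  No CRS handling is done — coordinates
stay in whatever system the inputs use.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("landgen")

#: dosages representable by a diploid genotype call
DIPLOID_DOSAGES = (0.0, 0.5, 1.0)
#: dosages representable on four chromosome copies
TETRAPLOID_DOSAGES = (0.0, 0.25, 0.5, 0.75, 1.0)

#: missing-value token used by all text formats
NA_TOKEN = "NA"


class LandgenError(Exception):
    """Base class for errors raised by this package."""


class ParseError(LandgenError):
    """A file could not be parsed as the declared format."""


class ValidationError(LandgenError):
    """Parsed data violate an invariant of the target type."""


# ---------------------------------------------------------------------------
# GenotypeMatrix
# ---------------------------------------------------------------------------


@dataclass
class GenotypeMatrix:
    """Individuals x loci alt-allele dosage matrix with missing entries.

    Parameters
    ----------
    sample_ids, locus_ids
        Unique row and column labels.
    dosage
        ``(n_samples, n_loci)`` float array; valid entries belong to
        ``allowed`` (default diploid {0, 0.5, 1}); missing entries are nan.
    """

    sample_ids: list[str]
    locus_ids: list[str]
    dosage: np.ndarray
    allowed: tuple[float, ...] = DIPLOID_DOSAGES

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        n, L = self.dosage.shape if self.dosage.ndim == 2 else (0, 0)
        if self.dosage.ndim != 2 or n < 1 or L < 1:
            raise ValidationError("genotype matrix needs >=1 sample and >=1 locus")
        if len(self.sample_ids) != n or len(self.locus_ids) != L:
            raise ValidationError("id lists do not match dosage shape")
        if len(set(self.sample_ids)) != n:
            raise ValidationError("duplicate sample ids")
        if len(set(self.locus_ids)) != L:
            raise ValidationError("duplicate locus ids")
        vals = self.dosage[np.isfinite(self.dosage)]
        if vals.size and not np.isin(vals, self.allowed).all():
            bad = vals[~np.isin(vals, self.allowed)][:5]
            raise ValidationError(f"invalid dosage values {bad!r}")

    # -- convenience -------------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_loci(self) -> int:
        return self.dosage.shape[1]

    @property
    def missing(self) -> np.ndarray:
        """Boolean mask of missing entries."""
        return np.isnan(self.dosage)

    def sample_index(self, ids) -> np.ndarray:
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            return np.array([pos[s] for s in ids], dtype=int)
        except KeyError as e:  # pragma: no cover - message only
            raise ValidationError(f"unknown sample id {e.args[0]!r}") from None

    def subset(self, samples=None, loci=None) -> "GenotypeMatrix":
        rows = np.arange(self.n_samples) if samples is None else np.asarray(samples)
        cols = np.arange(self.n_loci) if loci is None else np.asarray(loci)
        return GenotypeMatrix(
            [self.sample_ids[i] for i in rows],
            [self.locus_ids[j] for j in cols],
            self.dosage[np.ix_(rows, cols)],
            allowed=self.allowed,
        )


# ---------------------------------------------------------------------------
# Sample metadata
# ---------------------------------------------------------------------------


@dataclass
class SampleTable:
    """Per-sample metadata: id, group (island/population) label, x/y coords."""

    df: pd.DataFrame

    REQUIRED = ("sample_id", "group", "x", "y")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.df.columns]
        if missing:
            raise ValidationError(f"sample table missing columns {missing}")
        if self.df["sample_id"].duplicated().any():
            raise ValidationError("duplicate sample ids in sample table")
        xy = self.df[["x", "y"]].to_numpy(dtype=float)
        if not np.isfinite(xy).all():
            raise ValidationError("non-finite coordinates in sample table")
        self.df = self.df.reset_index(drop=True)

    def coords(self, sample_ids) -> np.ndarray:
        sub = self.df.set_index("sample_id").loc[list(sample_ids)]
        return sub[["x", "y"]].to_numpy(dtype=float)

    def groups(self, sample_ids) -> np.ndarray:
        return (
            self.df.set_index("sample_id").loc[list(sample_ids), "group"].to_numpy()
        )


def read_sample_table(path) -> SampleTable:
    df = pd.read_csv(path, dtype={"sample_id": str, "group": str})
    return SampleTable(df)


def write_sample_table(table: SampleTable, path) -> None:
    table.df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Genotype formats
# ---------------------------------------------------------------------------


def read_genotypes(path, format: str = "dosage012") -> GenotypeMatrix:
    """Read a genotype matrix from a minimal VCF or a 0/1/2 dosage TSV.

    Diploid genotypes 0/1/2 become dosages 0/0.5/1; missing calls become
    nan.  Multi-allelic VCF records are skipped (count logged).
    """
    if format == "vcf":
        return _read_vcf(str(path))
    if format == "dosage012":
        return _read_dosage012(str(path))
    raise ValueError(f"unknown genotype format {format!r}")


def _read_vcf(path: str) -> GenotypeMatrix:
    import cyvcf2

    with open(path) as fh:
        first = fh.readline()
    if not first.startswith("##fileformat"):
        raise ParseError(f"{path}: line 1 is not a VCF ##fileformat header")
    try:
        vcf = cyvcf2.VCF(path)
    except Exception as e:  # htslib raises bare Exceptions
        raise ParseError(f"{path}: VCF header could not be parsed: {e}") from e
    samples = list(vcf.samples)
    if len(set(samples)) != len(samples):
        raise ValidationError(f"{path}: duplicate sample ids in VCF header")
    cols: list[np.ndarray] = []
    locus_ids: list[str] = []
    n_multiallelic = 0
    # cyvcf2 gt_types: 0=hom-ref 1=het 2=unknown 3=hom-alt
    gt_map = np.array([0.0, 0.5, np.nan, 1.0])
    for v in vcf:
        if len(v.ALT) != 1:
            n_multiallelic += 1
            continue
        lid = v.ID if v.ID not in (None, ".") else f"{v.CHROM}:{v.POS}"
        locus_ids.append(lid)
        cols.append(gt_map[np.asarray(v.gt_types)])
    vcf.close()
    if n_multiallelic:
        logger.info("skipped %d multi-allelic records in %s", n_multiallelic, path)
    if not cols:
        raise ParseError(f"{path}: no usable biallelic records")
    gm = GenotypeMatrix(samples, locus_ids, np.column_stack(cols))
    gm.n_multiallelic_skipped = n_multiallelic  # type: ignore[attr-defined]
    return gm


def _read_dosage012(path: str) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=[NA_TOKEN], dtype=str)
    dosage = df.to_numpy(dtype=float) / 2.0
    return GenotypeMatrix(
        [str(s) for s in df.index], [str(l) for l in df.columns], dosage
    )


def write_genotypes(gm: GenotypeMatrix, path, format: str = "dosage012") -> None:
    if format == "dosage012":
        counts = gm.dosage * 2.0
        df = pd.DataFrame(counts, index=gm.sample_ids, columns=gm.locus_ids)
        df.index.name = "sample_id"
        # integers where called, NA where missing
        df.to_csv(path, sep="\t", na_rep=NA_TOKEN, float_format="%.0f")
    elif format == "vcf":
        _write_vcf(gm, str(path))
    else:
        raise ValueError(f"unknown genotype format {format!r}")


_GT_STRINGS = {0.0: "0/0", 0.5: "0/1", 1.0: "1/1"}


def _write_vcf(gm: GenotypeMatrix, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.sample_ids)
            + "\n"
        )
        for j, lid in enumerate(gm.locus_ids):
            gts = [
                _GT_STRINGS.get(d, "./.") if np.isfinite(d) else "./."
                for d in gm.dosage[:, j]
            ]
            fh.write(f"1\t{j + 1}\t{lid}\tA\tT\t.\t.\t.\tGT\t" + "\t".join(gts) + "\n")


# ---------------------------------------------------------------------------
# ESRI ASCII rasters
# ---------------------------------------------------------------------------


@dataclass
class EnvRaster:
    """One environmental variable on a regular grid.

    ``values`` is ``(nrows, ncols)`` with row 0 the northernmost row; nodata
    cells are stored as nan and written back using ``nodata``.
    """

    ncols: int
    nrows: int
    xll: float
    yll: float
    cellsize: float
    nodata: float
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.nrows, self.ncols):
            raise ValidationError(
                f"raster shape {self.values.shape} != ({self.nrows}, {self.ncols})"
            )
        if self.cellsize <= 0:
            raise ValidationError("cellsize must be positive")

    # -- geometry ----------------------------------------------------------

    def x_centers(self) -> np.ndarray:
        return self.xll + (np.arange(self.ncols) + 0.5) * self.cellsize

    def y_centers(self) -> np.ndarray:
        """Cell-center northings, ordered like the rows (north first)."""
        return self.yll + (self.nrows - np.arange(self.nrows) - 0.5) * self.cellsize

    def cell_of(self, x: float, y: float) -> tuple[int, int]:
        col = int((x - self.xll) / self.cellsize)
        row = self.nrows - 1 - int((y - self.yll) / self.cellsize)
        if not (0 <= row < self.nrows and 0 <= col < self.ncols):
            raise ValidationError(f"point ({x}, {y}) outside raster extent")
        return row, col

    def value_at(self, x: float, y: float) -> float:
        r, c = self.cell_of(x, y)
        return float(self.values[r, c])

    def same_grid(self, other: "EnvRaster") -> bool:
        return (
            self.ncols == other.ncols
            and self.nrows == other.nrows
            and np.isclose(self.xll, other.xll)
            and np.isclose(self.yll, other.yll)
            and np.isclose(self.cellsize, other.cellsize)
        )

    def copy_with(self, values: np.ndarray) -> "EnvRaster":
        return EnvRaster(
            self.ncols, self.nrows, self.xll, self.yll, self.cellsize, self.nodata,
            np.asarray(values, dtype=float),
        )


_HEADER_KEYS = {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"}


def read_raster(path) -> EnvRaster:
    """Read an ESRI ASCII grid (header keys case-insensitive)."""
    header: dict[str, float] = {}
    body: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if key in _HEADER_KEYS and len(parts) == 2 and not body:
                header[key] = float(parts[1])
            else:
                try:
                    body.extend(float(p) for p in parts)
                except ValueError as e:
                    raise ParseError(f"{path}: line {lineno}: {e}") from None
    for k in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if k not in header:
            raise ParseError(f"{path}: missing header key {k}")
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    nodata = header.get("nodata_value", -9999.0)
    if len(body) != ncols * nrows:
        raise ParseError(
            f"{path}: expected {ncols * nrows} values, found {len(body)}"
        )
    values = np.array(body, dtype=float).reshape(nrows, ncols)
    values[values == nodata] = np.nan
    return EnvRaster(
        ncols, nrows, header["xllcorner"], header["yllcorner"],
        header["cellsize"], nodata, values,
    )


def write_raster(raster: EnvRaster, path) -> None:
    vals = raster.values.copy()
    vals[np.isnan(vals)] = raster.nodata
    with open(path, "w") as fh:
        fh.write(f"ncols {raster.ncols}\n")
        fh.write(f"nrows {raster.nrows}\n")
        fh.write(f"xllcorner {raster.xll:.10g}\n")
        fh.write(f"yllcorner {raster.yll:.10g}\n")
        fh.write(f"cellsize {raster.cellsize:.10g}\n")
        fh.write(f"NODATA_value {raster.nodata:.10g}\n")
        for row in vals:
            fh.write(" ".join(f"{v:.10g}" for v in row) + "\n")
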