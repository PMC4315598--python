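"""Microsatellite genotype datasets: domain types, validation, and file formats.

The pipeline's universal input is a :class:`MicrosatDataset` — diploid
multilocus genotypes (allele fragment sizes in base pairs) with per-sample
spatial and temporal metadata (planar x/y in meters, city-block label,
collection year).  This module reads and writes the CSV dialects the
pipeline touches and the two interchange formats downstream clustering
tools expect (GenePop, STRUCTURE), and provides the allele-size binning
step that snaps raw fragment sizes onto the repeat-unit grid.

Conventions
-----------
* Genotypes are unordered: allele pairs are sorted ascending on ingest
  (microsatellites carry no phase).
* Missing data has a single in-memory sentinel (``None`` for the locus);
  format-specific codes (``000000``, ``-9``, empty cells) are translated
  at the I/O boundary.
* Coordinates are planar meters in a projected frame; deposited genotype
  files may lack metadata entirely (coordinates withheld for privacy), so
  the reader tolerates metadata-free tables and downstream operations that
  need coordinates raise :class:`MissingMetadataError`.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

__all__ = [
    "LocusDef",
    "SampleRecord",
    "MicrosatDataset",
    "Genotype",
    "GenotypeIOError",
    "ParseError",
    "ValidationError",
    "MissingMetadataError",
    "read_genotype_table",
    "write_genotype_table",
    "write_genepop",
    "write_structure_input",
    "read_genepop",
    "bin_alleles",
]

#: An unordered diploid genotype at one locus: (smaller, larger) allele size
#: in bp, or None when the locus failed to amplify.
Genotype = Optional[tuple[int, int]]

#: Strings accepted as a missing allele in CSV input.
_MISSING_TOKENS = {"", "na", "nan", "none", "0", "-9", "000"}


class GenotypeIOError(Exception):
    """Base class for dataset I/O and validation failures."""


class ParseError(GenotypeIOError):
    """A malformed row or field; the message names the row and column."""


class ValidationError(GenotypeIOError):
    """A dataset invariant is violated."""


class MissingMetadataError(GenotypeIOError):
    """An operation needs coordinates/blocks/years the dataset lacks."""


@dataclass(frozen=True)
class LocusDef:
    """A microsatellite locus: its label, repeat unit, and binning anchor.

    ``repeat_size`` is the tandem-repeat unit in bp (e.g. 2 for a
    dinucleotide); ``reference_offset`` anchors the allele-size grid, so
    every binned allele is congruent to it modulo ``repeat_size``.
    """

    name: str
    repeat_size: int = 1
    reference_offset: int = 0

    def __post_init__(self) -> None:
        if not self.name:
            raise ValidationError("locus name must be non-empty")
        if self.repeat_size < 1:
            raise ValidationError(
                f"locus {self.name!r}: repeat_size must be >= 1, got {self.repeat_size}"
            )
        if self.reference_offset < 0:
            raise ValidationError(
                f"locus {self.name!r}: reference_offset must be >= 0"
            )


@dataclass
class SampleRecord:
    """One sampled individual: id, location, block, year, multilocus genotype.

    ``genotype`` is a tuple with one entry per locus, in dataset locus
    order; each entry is a sorted ``(a1, a2)`` pair of allele sizes in bp
    or ``None`` for a missing locus.  ``x``/``y`` may be ``None`` when the
    source table carries no coordinates.
    """

    sample_id: str
    x: Optional[float]
    y: Optional[float]
    block_id: Optional[str]
    year: Optional[int]
    genotype: tuple[Genotype, ...]

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValidationError("sample_id must be non-empty")
        for coord, label in ((self.x, "x"), (self.y, "y")):
            if coord is not None and not math.isfinite(coord):
                raise ValidationError(
                    f"sample {self.sample_id!r}: coordinate {label} is not finite"
                )
        geno = []
        for k, g in enumerate(self.genotype):
            if g is None:
                geno.append(None)
                continue
            if len(g) != 2:
                raise ValidationError(
                    f"sample {self.sample_id!r}, locus index {k}: "
                    f"a diploid genotype needs exactly 2 alleles, got {len(g)}"
                )
            a, b = int(g[0]), int(g[1])
            if a <= 0 or b <= 0:
                raise ValidationError(
                    f"sample {self.sample_id!r}, locus index {k}: "
                    f"allele sizes must be > 0, got {g}"
                )
            geno.append((min(a, b), max(a, b)))
        self.genotype = tuple(geno)

    @property
    def has_coordinates(self) -> bool:
        return self.x is not None and self.y is not None


@dataclass
class MicrosatDataset:
    """An ordered locus list plus sample records; the pipeline's input type."""

    loci: tuple[LocusDef, ...]
    samples: tuple[SampleRecord, ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        self.loci = tuple(self.loci)
        self.samples = tuple(self.samples)
        self.validate()

    # -- validation -----------------------------------------------------

    def validate(self) -> None:
        if len(self.loci) < 1:
            raise ValidationError("dataset must have at least 1 locus")
        if len(self.samples) < 1:
            raise ValidationError("dataset must have at least 1 sample")
        names = [l.name for l in self.loci]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValidationError(f"duplicate locus names: {dupes}")
        seen: set[str] = set()
        for s in self.samples:
            if s.sample_id in seen:
                raise ValidationError(f"duplicate sample_id {s.sample_id!r}")
            seen.add(s.sample_id)
            if len(s.genotype) != len(self.loci):
                raise ValidationError(
                    f"sample {s.sample_id!r}: genotype has {len(s.genotype)} loci, "
                    f"dataset defines {len(self.loci)}"
                )
        # allele grid congruence per locus
        for k, locus in enumerate(self.loci):
            if locus.repeat_size == 1:
                continue
            for s in self.samples:
                g = s.genotype[k]
                if g is None:
                    continue
                for a in g:
                    if (a - locus.reference_offset) % locus.repeat_size != 0:
                        raise ValidationError(
                            f"sample {s.sample_id!r}, locus {locus.name!r}: allele {a} "
                            f"is off the repeat grid (offset {locus.reference_offset}, "
                            f"unit {locus.repeat_size})"
                        )

    # -- conveniences ---------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def locus_names(self) -> list[str]:
        return [l.name for l in self.loci]

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def has_coordinates(self) -> bool:
        return all(s.has_coordinates for s in self.samples)

    def years(self) -> list[int]:
        """Distinct collection years present, sorted."""
        ys = {s.year for s in self.samples if s.year is not None}
        return sorted(ys)

    def subset(self, indices: Sequence[int], provenance: str = "") -> "MicrosatDataset":
        return MicrosatDataset(
            loci=self.loci,
            samples=tuple(self.samples[i] for i in indices),
            provenance=provenance or self.provenance,
        )

    def with_genotypes(self, genotypes: Sequence[tuple[Genotype, ...]]) -> "MicrosatDataset":
        """A copy with sample genotypes replaced (metadata fixed) — the
        permutation test's workhorse."""
        if len(genotypes) != self.n_samples:
            raise ValidationError("genotype list length must match sample count")
        samples = tuple(
            replace(s, genotype=g) for s, g in zip(self.samples, genotypes)
        )
        return MicrosatDataset(self.loci, samples, self.provenance)


# ---------------------------------------------------------------------------
# allele binning
# ---------------------------------------------------------------------------

def bin_alleles(raw_sizes: Iterable[float], locus: LocusDef) -> list[int]:
    """Snap raw (fractional-bp) fragment sizes onto the locus repeat grid.

    Each size maps to ``offset + round((size - offset)/unit) * unit`` with
    round-half-up on the repeat-unit scale, so a fragment exactly half-way
    between two grid points bins to the larger allele.  Idempotent on
    already-binned sizes.
    """
    out = []
    for size in raw_sizes:
        if size <= 0:
            raise ValidationError(f"raw allele size must be > 0, got {size}")
        units = math.floor((size - locus.reference_offset) / locus.repeat_size + 0.5)
        out.append(locus.reference_offset + units * locus.repeat_size)
    return out


# ---------------------------------------------------------------------------
# CSV genotype tables (wide and long dialects)
# ---------------------------------------------------------------------------

_META_COLS = ("sample_id", "x", "y", "block_id", "year")


def _parse_allele(token: str, row_label: str, col: str) -> Optional[int]:
    tok = token.strip()
    if tok.lower() in _MISSING_TOKENS:
        return None
    try:
        val = float(tok)
    except ValueError:
        raise ParseError(f"row {row_label}: column {col!r}: cannot parse allele {token!r}")
    if val != int(val):
        raise ParseError(
            f"row {row_label}: column {col!r}: allele {token!r} is not an integer "
            "(bin raw sizes first)"
        )
    return int(val)


def _parse_meta(row: dict, row_label: str) -> dict:
    meta: dict = {"x": None, "y": None, "block_id": None, "year": None}
    for key in ("x", "y"):
        tok = (row.get(key) or "").strip()
        if tok and tok.lower() not in {"na", "nan", "none"}:
            try:
                meta[key] = float(tok)
            except ValueError:
                raise ParseError(f"row {row_label}: column {key!r}: bad coordinate {tok!r}")
    blk = (row.get("block_id") or "").strip()
    if blk:
        meta["block_id"] = blk
    yr = (row.get("year") or "").strip()
    if yr:
        try:
            meta["year"] = int(yr)
        except ValueError:
            raise ParseError(f"row {row_label}: column 'year': bad year {yr!r}")
    return meta


def read_genotype_table(
    path: str | Path,
    dialect: str = "wide",
    loci: Optional[Sequence[LocusDef]] = None,
) -> MicrosatDataset:
    """Read a CSV genotype table in the *wide* or *long* dialect.

    Wide: one row per sample; columns ``sample_id, x, y, block_id, year``
    then ``<locus>_a1, <locus>_a2`` per locus.  Long: one row per
    sample x locus with columns ``sample_id, x, y, block_id, year, locus,
    a1, a2``.  Metadata columns are optional (privacy-redacted deposits).

    ``loci`` optionally supplies repeat sizes / binning anchors for the
    locus names found in the file; unlisted loci default to a unit grid.
    """
    path = Path(path)
    if dialect not in {"wide", "long"}:
        raise ValueError(f"unknown dialect {dialect!r}; use 'wide' or 'long'")
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise ParseError(f"{path}: empty file, header required")
        rows = list(reader)
    if not rows:
        raise ParseError(f"{path}: no data rows")

    locus_by_name = {l.name: l for l in (loci or [])}

    def locus_def(name: str) -> LocusDef:
        return locus_by_name.get(name, LocusDef(name=name))

    if dialect == "wide":
        header = reader.fieldnames
        locus_names: list[str] = []
        for col in header:
            if col in _META_COLS:
                continue
            if col.endswith("_a1"):
                locus_names.append(col[:-3])
            elif col.endswith("_a2"):
                if col[:-3] not in locus_names:
                    raise ParseError(
                        f"{path}: column {col!r} has no matching {col[:-3]}_a1"
                    )
            else:
                raise ParseError(f"{path}: unrecognized column {col!r}")
        for name in locus_names:
            if f"{name}_a2" not in header:
                raise ParseError(f"{path}: locus {name!r} lacks an _a2 column")
        if not locus_names:
            raise ParseError(f"{path}: no locus columns found")
        samples = []
        for i, row in enumerate(rows, start=2):
            sid = (row.get("sample_id") or "").strip()
            if not sid:
                raise ParseError(f"row {i}: missing sample_id")
            meta = _parse_meta(row, str(i))
            geno: list[Genotype] = []
            for name in locus_names:
                a1 = _parse_allele(row.get(f"{name}_a1", ""), str(i), f"{name}_a1")
                a2 = _parse_allele(row.get(f"{name}_a2", ""), str(i), f"{name}_a2")
                if (a1 is None) != (a2 is None):
                    raise ParseError(
                        f"row {i}: locus {name!r} has one allele missing — a diploid "
                        "locus needs 2 alleles or none"
                    )
                geno.append(None if a1 is None else (a1, a2))
            samples.append(SampleRecord(sid, genotype=tuple(geno), **meta))
        return MicrosatDataset(
            loci=tuple(locus_def(n) for n in locus_names),
            samples=tuple(samples),
            provenance=str(path),
        )

    # long dialect: group rows by sample_id preserving first-appearance order
    required = {"sample_id", "locus", "a1", "a2"}
    missing = required - set(reader.fieldnames)
    if missing:
        raise ParseError(f"{path}: long dialect lacks columns {sorted(missing)}")
    locus_names = []
    per_sample: dict[str, dict] = {}
    order: list[str] = []
    for i, row in enumerate(rows, start=2):
        sid = (row.get("sample_id") or "").strip()
        lname = (row.get("locus") or "").strip()
        if not sid or not lname:
            raise ParseError(f"row {i}: sample_id and locus are required")
        if lname not in locus_names:
            locus_names.append(lname)
        if sid not in per_sample:
            per_sample[sid] = {"meta": _parse_meta(row, str(i)), "geno": {}}
            order.append(sid)
        if lname in per_sample[sid]["geno"]:
            raise ParseError(f"row {i}: duplicate locus {lname!r} for sample {sid!r}")
        a1 = _parse_allele(row.get("a1", ""), str(i), "a1")
        a2 = _parse_allele(row.get("a2", ""), str(i), "a2")
        if (a1 is None) != (a2 is None):
            raise ParseError(f"row {i}: locus {lname!r} has one allele missing")
        per_sample[sid]["geno"][lname] = None if a1 is None else (a1, a2)
    samples = []
    for sid in order:
        entry = per_sample[sid]
        geno = tuple(entry["geno"].get(n) for n in locus_names)
        samples.append(SampleRecord(sid, genotype=geno, **entry["meta"]))
    return MicrosatDataset(
        loci=tuple(locus_def(n) for n in locus_names),
        samples=tuple(samples),
        provenance=str(path),
    )


def write_genotype_table(ds: MicrosatDataset, path: str | Path) -> Path:
    """Write the wide CSV dialect (the pipeline's canonical on-disk form)."""
    path = Path(path)
    header = list(_META_COLS)
    for l in ds.loci:
        header += [f"{l.name}_a1", f"{l.name}_a2"]
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(header)
        for s in ds.samples:
            row = [
                s.sample_id,
                "" if s.x is None else repr(float(s.x)),
                "" if s.y is None else repr(float(s.y)),
                s.block_id or "",
                "" if s.year is None else s.year,
            ]
            for g in s.genotype:
                row += ["", ""] if g is None else [g[0], g[1]]
            w.writerow(row)
    return path


# ---------------------------------------------------------------------------
# GenePop / STRUCTURE interchange
# ---------------------------------------------------------------------------

def write_genepop(ds: MicrosatDataset, path: str | Path, title: str = "") -> Path:
    """Write GenePop 4 (6-digit diploid codes, one POP per city block).

    Alleles above 999 bp cannot be encoded in 3 digits per allele and raise
    an explicit overflow error.  Missing loci are written ``000000``.
    """
    path = Path(path)
    for s in ds.samples:
        for locus, g in zip(ds.loci, s.genotype):
            if g is not None and max(g) > 999:
                raise ValidationError(
                    f"sample {s.sample_id!r}, locus {locus.name!r}: allele {max(g)} "
                    "exceeds the GenePop 3-digit-per-allele limit (999)"
                )
    blocks: dict[str, list[SampleRecord]] = {}
    for s in ds.samples:
        blocks.setdefault(s.block_id or "NA", []).append(s)
    lines = [title or (ds.provenance or "urbanbarrier genotype export")]
    lines += [l.name for l in ds.loci]
    for _, members in blocks.items():
        lines.append("POP")
        for s in members:
            codes = [
                "000000" if g is None else f"{g[0]:03d}{g[1]:03d}" for g in s.genotype
            ]
            lines.append(f"{s.sample_id} , " + " ".join(codes))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def read_genepop(path: str | Path) -> MicrosatDataset:
    """Read a GenePop file written by :func:`write_genepop`.

    Coordinates and years are not representable in GenePop; block labels
    are recovered as ``POP1, POP2, ...`` only if the ids do not carry them,
    so the round-trip contract covers loci, sample ids, and genotypes.
    """
    path = Path(path)
    lines = [ln.rstrip("\n") for ln in path.read_text(encoding="utf-8").splitlines()]
    if len(lines) < 3:
        raise ParseError(f"{path}: too short for a GenePop file")
    locus_names: list[str] = []
    i = 1
    while i < len(lines) and lines[i].strip().upper() != "POP":
        name = lines[i].strip()
        if name:
            # allow the comma-separated single-line locus list variant
            if "," in name:
                locus_names.extend(t.strip() for t in name.split(",") if t.strip())
            else:
                locus_names.append(name)
        i += 1
    if not locus_names:
        raise ParseError(f"{path}: no locus names before first POP")
    samples: list[SampleRecord] = []
    pop_idx = 0
    while i < len(lines):
        if lines[i].strip().upper() == "POP":
            pop_idx += 1
            i += 1
            continue
        line = lines[i].strip()
        i += 1
        if not line:
            continue
        if "," not in line:
            raise ParseError(f"{path}: line {i}: expected 'id , genotypes'")
        sid, rest = line.split(",", 1)
        codes = rest.split()
        if len(codes) != len(locus_names):
            raise ParseError(
                f"{path}: line {i}: sample {sid.strip()!r} has {len(codes)} genotype "
                f"fields, expected {len(locus_names)}"
            )
        geno: list[Genotype] = []
        for code in codes:
            if len(code) != 6 or not code.isdigit():
                raise ParseError(f"{path}: line {i}: bad 6-digit code {code!r}")
            a1, a2 = int(code[:3]), int(code[3:])
            if a1 == 0 and a2 == 0:
                geno.append(None)
            elif a1 == 0 or a2 == 0:
                raise ParseError(f"{path}: line {i}: half-missing code {code!r}")
            else:
                geno.append((a1, a2))
        samples.append(
            SampleRecord(
                sample_id=sid.strip(),
                x=None,
                y=None,
                block_id=f"POP{pop_idx}",
                year=None,
                genotype=tuple(geno),
            )
        )
    return MicrosatDataset(
        loci=tuple(LocusDef(n) for n in locus_names),
        samples=tuple(samples),
        provenance=str(path),
    )


def write_structure_input(ds: MicrosatDataset, path: str | Path) -> Path:
    """Write STRUCTURE's two-rows-per-individual input (missing = -9).

    Columns are tab-separated: sample id then one allele per locus in
    dataset order; each individual contributes two rows (one allele each).
    """
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(l.name for l in ds.loci) + "\n")
        for s in ds.samples:
            for which in (0, 1):
                alleles = [
                    "-9" if g is None else str(g[which]) for g in s.genotype
                ]
                fh.write("\t".join([s.sample_id] + alleles) + "\n")
    return path
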