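"""Core data containers and readers/writers for Genepop and FASTA inputs.

The pipeline works with three in-memory containers:

``GenotypeTable``
    diploid codominant genotypes (microsatellite allele sizes) for one or
    more populations, with missing-data support;
``HaplotypeAlignment``
    an equal-length mtDNA alignment with per-sequence group annotations
    (hybrid-zone sample vs. named reference clade);
``PopulationMap``
    ordered population labels with diploid sample sizes.

Genotypes travel as Genepop files (the native format of the classic
population-genetics tools this pipeline mirrors), alignments as FASTA with
annotations either in a ``id|group`` header convention or a sidecar CSV.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

MISSING = 0  # allele-state sentinel for a missing call ("000" in Genepop)


class GenepopFormatError(ValueError):
    """Raised when a Genepop file violates the accepted dialect."""


class AlignmentError(ValueError):
    """Raised for ragged or otherwise invalid alignments."""


@dataclass
class PopulationMap:
    """Ordered population labels with diploid sample sizes."""

    labels: list[str]
    sizes: dict[str, int]

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("population labels must be unique")
        for lab in self.labels:
            if self.sizes.get(lab, 0) <= 0:
                raise ValueError(f"population {lab!r} must have positive size")

    @property
    def n_total(self) -> int:
        return sum(self.sizes[l] for l in self.labels)


@dataclass
class GenotypeTable:
    """Diploid allele-size matrix with population labels and missing mask.

    ``alleles`` has shape ``(n_individuals, n_loci, 2)`` with positive
    integer allele states (fragment or repeat sizes); both entries equal to
    ``MISSING`` (0) encode a missing call.  A half-missing call is invalid.
    """

    individuals: list[str]
    pops: list[str]  # one label per individual, aligned with `individuals`
    loci: list[str]
    alleles: np.ndarray

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int32)
        n, L = len(self.individuals), len(self.loci)
        if self.alleles.shape != (n, L, 2):
            raise ValueError(
                f"allele array shape {self.alleles.shape} does not match "
                f"{n} individuals x {L} loci x 2"
            )
        if len(self.pops) != n:
            raise ValueError("one population label per individual required")
        half = (self.alleles == MISSING).sum(axis=2) == 1
        if half.any():
            raise ValueError("half-missing calls are not allowed")
        if (self.alleles < 0).any():
            raise ValueError("allele states must be positive (0 = missing)")

    @property
    def pop_labels(self) -> list[str]:
        """Population labels in order of first appearance."""
        seen: dict[str, None] = {}
        for p in self.pops:
            seen.setdefault(p)
        return list(seen)

    @property
    def missing(self) -> np.ndarray:
        """Boolean mask (n, L): True where the call is missing."""
        return self.alleles[:, :, 0] == MISSING

    def pop_mask(self, pop: str) -> np.ndarray:
        cache = self.__dict__.setdefault("_mask_cache", {})
        if pop not in cache:
            if pop not in self.pops:
                raise KeyError(f"unknown population {pop!r}")
            cache[pop] = np.array([p == pop for p in self.pops])
        return cache[pop]

    def subset_pop(self, pop: str) -> "GenotypeTable":
        m = self.pop_mask(pop)
        return GenotypeTable(
            [i for i, k in zip(self.individuals, m) if k],
            [pop] * int(m.sum()),
            list(self.loci),
            self.alleles[m],
        )

    def population_map(self) -> PopulationMap:
        labels = self.pop_labels
        sizes = {l: int(self.pop_mask(l).sum()) for l in labels}
        return PopulationMap(labels, sizes)

    def __eq__(self, other: object) -> bool:  # value equality for round-trips
        if not isinstance(other, GenotypeTable):
            return NotImplemented
        return (
            self.individuals == other.individuals
            and self.pops == other.pops
            and self.loci == other.loci
            and np.array_equal(self.alleles, other.alleles)
        )


@dataclass
class HaplotypeAlignment:
    """Equal-length sequence set with per-record group annotations.

    ``annotation`` maps a sequence id to either ``"hybrid-zone"`` or a
    reference clade label of the form ``"reference:<clade>"``.
    """

    ids: list[str]
    seqs: list[str]
    annotation: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.ids)) != len(self.ids):
            raise AlignmentError("sequence identifiers must be unique")
        lengths = {len(s) for s in self.seqs}
        if len(self.seqs) and len(lengths) != 1:
            bad = [i for i, s in zip(self.ids, self.seqs) if len(s) != len(self.seqs[0])]
            raise AlignmentError(f"unequal sequence lengths for: {', '.join(bad)}")
        self.seqs = [s.upper() for s in self.seqs]

    @property
    def length(self) -> int:
        return len(self.seqs[0]) if self.seqs else 0

    def __len__(self) -> int:
        return len(self.ids)

    def subset(self, ids: Sequence[str]) -> "HaplotypeAlignment":
        idx = {i: k for k, i in enumerate(self.ids)}
        keep = [idx[i] for i in ids]
        return HaplotypeAlignment(
            [self.ids[k] for k in keep],
            [self.seqs[k] for k in keep],
            {self.ids[k]: self.annotation[self.ids[k]]
             for k in keep if self.ids[k] in self.annotation},
        )


# ---------------------------------------------------------------------------
# Genepop

_POP_RE = re.compile(r"^\s*pop\s*$", re.IGNORECASE)
_TITLE_POPS_RE = re.compile(r"pops\s*[:=]\s*([\w,\- ]+)")


def read_genepop(path: str | Path) -> GenotypeTable:
    """Read a Genepop file into a :class:`GenotypeTable`.

    Dialect: a title line; locus names one per line or comma-separated;
    ``POP`` separators; individual lines ``id , a1a2 a1a2 ...`` with a
    uniform 2- or 3-digit per-allele encoding.  ``00``/``000`` per allele
    means missing; a half-missing call is coerced to fully missing with a
    warning.  Population labels are taken from a ``pops: A,B,C`` hint on the
    title line when present, else ``pop1..popK``.
    """
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise GenepopFormatError("empty file")
    title = lines[0]
    pop_labels_hint: list[str] | None = None
    m = _TITLE_POPS_RE.search(title)
    if m:
        pop_labels_hint = [s.strip() for s in m.group(1).split(",") if s.strip()]

    # locus names run until the first POP line
    loci: list[str] = []
    i = 1
    while i < len(lines) and not _POP_RE.match(lines[i]):
        chunk = lines[i].strip()
        if chunk:
            loci.extend(s.strip() for s in chunk.split(",") if s.strip())
        i += 1
    if i == len(lines):
        raise GenepopFormatError("no POP separator found")
    if not loci:
        raise GenepopFormatError("no locus names before first POP")

    individuals: list[str] = []
    pops: list[str] = []
    rows: list[list[tuple[int, int]]] = []
    width: int | None = None
    pop_idx = 0
    for lineno in range(i, len(lines)):
        line = lines[lineno]
        if _POP_RE.match(line):
            pop_idx += 1
            continue
        if not line.strip():
            continue
        if "," in line:
            ident, _, rest = line.partition(",")
        else:  # tolerate missing comma: first token is the id
            ident, _, rest = line.strip().partition(" ")
        ident = ident.strip()
        tokens = rest.split()
        if len(tokens) != len(loci):
            raise GenepopFormatError(
                f"line {lineno + 1}: expected {len(loci)} loci, got {len(tokens)}"
            )
        calls: list[tuple[int, int]] = []
        for tok in tokens:
            if len(tok) not in (4, 6) or not tok.isdigit():
                raise GenepopFormatError(
                    f"line {lineno + 1}: malformed genotype token {tok!r}"
                )
            w = len(tok) // 2
            if width is None:
                width = w
            elif w != width:
                raise GenepopFormatError(
                    f"line {lineno + 1}: mixed {2}- and {3}-digit allele "
                    "encodings within one file"
                )
            a1, a2 = int(tok[:w]), int(tok[w:])
            if (a1 == 0) != (a2 == 0):
                logger.warning(
                    "half-missing call %r for %s coerced to missing", tok, ident
                )
                a1 = a2 = 0
            calls.append((a1, a2))
        individuals.append(ident)
        pops.append(f"pop{pop_idx}")
        rows.append(calls)

    if not individuals:
        raise GenepopFormatError("no individuals found")
    n_pops = pop_idx
    if pop_labels_hint and len(pop_labels_hint) == n_pops:
        rename = {f"pop{k + 1}": lab for k, lab in enumerate(pop_labels_hint)}
        pops = [rename[p] for p in pops]
    alleles = np.array(rows, dtype=np.int32)
    return GenotypeTable(individuals, pops, loci, alleles)


def write_genepop(table: GenotypeTable, path: str | Path,
                  title: str | None = None) -> Path:
    """Write a :class:`GenotypeTable` as Genepop with 3-digit alleles.

    Population labels are recorded on the title line (``pops: A,B,C``) so
    that ``read_genepop`` round-trips the table exactly.
    """
    if not table.individuals:
        raise ValueError("cannot write an empty table")
    if (table.alleles > 999).any():
        raise ValueError("allele states above 999 cannot be 3-digit encoded")
    labels = table.pop_labels
    lines = [
        (title or "anole-admix genepop") + " ; pops: " + ",".join(labels)
    ]
    lines.extend(table.loci)
    for lab in labels:
        lines.append("POP")
        for k in np.flatnonzero(table.pop_mask(lab)):
            toks = [
                f"{table.alleles[k, j, 0]:03d}{table.alleles[k, j, 1]:03d}"
                for j in range(len(table.loci))
            ]
            lines.append(f"{table.individuals[k]} , " + " ".join(toks))
    out = Path(path)
    out.write_text("\n".join(lines) + "\n")
    return out


# ---------------------------------------------------------------------------
# FASTA alignments

def read_fasta_alignment(path: str | Path,
                         annotations: str | Path | Mapping[str, str] | None = None,
                         ) -> HaplotypeAlignment:
    """Read an aligned FASTA into a :class:`HaplotypeAlignment`.

    Annotations come from, in order of precedence: an explicit mapping, a
    sidecar CSV path with ``id,group`` rows, or a ``>id|group`` header
    convention.  Records without any of these get no annotation.
    """
    ids, seqs, anno = [], [], {}
    for rec in SeqIO.parse(str(path), "fasta"):
        ident = rec.id
        if "|" in ident:
            ident, _, group = ident.partition("|")
            anno[ident] = group
        ids.append(ident)
        seqs.append(str(rec.seq).upper())
    if annotations is not None:
        if isinstance(annotations, Mapping):
            anno.update(annotations)
        else:
            for line in Path(annotations).read_text().splitlines():
                line = line.strip()
                if not line or line.lower().startswith("id,"):
                    continue
                ident, _, group = line.partition(",")
                anno[ident.strip()] = group.strip()
    aln = HaplotypeAlignment(ids, seqs, {i: g for i, g in anno.items() if i in ids})
    return aln


def write_fasta_alignment(aln: HaplotypeAlignment, path: str | Path,
                          embed_groups: bool = False) -> Path:
    """Write an alignment as FASTA; optionally embed groups as ``id|group``."""
    out = Path(path)
    with out.open("w") as fh:
        for ident, seq in zip(aln.ids, aln.seqs):
            header = ident
            if embed_groups and ident in aln.annotation:
                header = f"{ident}|{aln.annotation[ident]}"
            fh.write(f">{header}\n{seq}\n")
    return out
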