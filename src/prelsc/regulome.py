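"""ChIP-seq peak handling and transcription-factor target signatures.

Peaks (BED, 0-based half-open) are assigned to genes whose transcription
start site (TSS) lies within a promoter-proximal window: a gene is a target
of a regulator iff at least one peak intersects the closed interval
``[TSS - window, TSS + window]`` (default window 2000 bp, i.e. the "2 kb
region around the TSS" convention).  Strand is used only to locate the TSS;
the window itself is symmetric and strand-agnostic.

Multiple datasets for one regulator can be merged by interval union or, for
"common in both cell lines" semantics, by gene-level intersection of the
per-dataset target sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import reduce
from pathlib import Path

from intervaltree import IntervalTree

from prelsc.errors import InputError

__all__ = [
    "PeakSet",
    "TSSAnnotation",
    "TFSignature",
    "assign_peaks_to_genes",
    "merge_peaksets",
    "merge_datasets",
    "build_signature",
    "read_bed",
    "read_tss",
    "write_bed",
    "DEFAULT_PROMOTER_WINDOW",
]

logger = logging.getLogger(__name__)

DEFAULT_PROMOTER_WINDOW = 2000


@dataclass(frozen=True)
class Peak:
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise InputError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}"
            )


@dataclass
class PeakSet:
    """Binding peaks for one regulator from one (or merged) dataset(s)."""

    regulator: str
    source: str
    peaks: list[Peak]

    def __len__(self) -> int:
        return len(self.peaks)


@dataclass
class TSSAnnotation:
    """gene id → (chromosome, TSS coordinate, strand).

    One primary TSS per gene; when a gene appears more than once the first
    listed annotation wins and the alternatives are logged.
    """

    tss: dict[str, tuple[str, int, str]] = field(default_factory=dict)

    def add(self, gene: str, chrom: str, pos: int, strand: str) -> None:
        if strand not in ("+", "-"):
            raise InputError(f"strand must be '+' or '-', got {strand!r}")
        if gene in self.tss:
            logger.info("gene %s has an alternative TSS; keeping the first", gene)
            return
        self.tss[gene] = (chrom, pos, strand)

    @property
    def genes(self) -> set[str]:
        return set(self.tss)

    def chromosomes(self) -> set[str]:
        return {chrom for chrom, _, _ in self.tss.values()}

    def __len__(self) -> int:
        return len(self.tss)


@dataclass
class TFSignature:
    """A regulator and the genes whose proximal promoters it binds."""

    regulator: str
    genes: frozenset[str]

    @property
    def empty(self) -> bool:
        return len(self.genes) == 0

    def __len__(self) -> int:
        return len(self.genes)


def assign_peaks_to_genes(
    peaks: PeakSet, tss: TSSAnnotation, window: int = DEFAULT_PROMOTER_WINDOW
) -> TFSignature:
    """Genes with ≥1 peak within ±``window`` bp of their TSS (closed window).

    A BED interval ``[start, end)`` intersects the closed promoter window
    ``[TSS - window, TSS + window]`` iff ``start <= TSS + window`` and
    ``end > TSS - window``; equivalently the nearest-edge distance is at most
    ``window``.  Peaks on chromosomes absent from the annotation are skipped
    with a warning.
    """
    if window <= 0:
        raise InputError("window must be positive")
    trees: dict[str, IntervalTree] = {}
    known_chroms = tss.chromosomes()
    skipped = 0
    for p in peaks.peaks:
        if p.chrom not in known_chroms:
            skipped += 1
            continue
        trees.setdefault(p.chrom, IntervalTree()).addi(p.start, p.end)
    if skipped:
        logger.warning(
            "%d peak(s) of %s on chromosomes absent from the annotation; skipped",
            skipped,
            peaks.regulator,
        )
    hit = set()
    for gene, (chrom, pos, _strand) in tss.tss.items():
        tree = trees.get(chrom)
        if tree is None:
            continue
        # closed window [pos-window, pos+window] vs half-open peak intervals:
        # query the half-open range [pos-window, pos+window+1)
        if tree.overlap(max(pos - window, 0), pos + window + 1):
            hit.add(gene)
    return TFSignature(regulator=peaks.regulator, genes=frozenset(hit))


def merge_peaksets(peaksets: list[PeakSet]) -> PeakSet:
    """Interval union of peaksets sharing one regulator label."""
    _check_same_regulator(peaksets)
    merged: list[Peak] = []
    for ps in peaksets:
        merged.extend(ps.peaks)
    source = "+".join(ps.source for ps in peaksets)
    return PeakSet(regulator=peaksets[0].regulator, source=source, peaks=merged)


def merge_datasets(peaksets: list[PeakSet], rule: str = "union") -> PeakSet:
    """Merge datasets at the interval level (union rule only).

    The intersection rule is defined at the gene level, after promoter
    assignment; use :func:`build_signature` with ``merge="intersection"``.
    """
    if rule != "union":
        raise InputError(
            "merge_datasets supports rule='union'; gene-level intersection is "
            "performed by build_signature(merge='intersection')"
        )
    return merge_peaksets(peaksets)


def build_signature(
    peaksets: list[PeakSet],
    tss: TSSAnnotation,
    window: int = DEFAULT_PROMOTER_WINDOW,
    merge: str = "union",
) -> TFSignature:
    """Target signature from one or more datasets of the same regulator.

    ``merge="union"`` pools all peaks before assignment; ``"intersection"``
    assigns each dataset separately and keeps genes that are targets in every
    dataset (the "peaks common in both cell lines" rule).
    """
    _check_same_regulator(peaksets)
    if merge == "union":
        return assign_peaks_to_genes(merge_peaksets(peaksets), tss, window)
    if merge == "intersection":
        sigs = [assign_peaks_to_genes(ps, tss, window) for ps in peaksets]
        genes = reduce(lambda a, b: a & b, (s.genes for s in sigs))
        return TFSignature(regulator=peaksets[0].regulator, genes=frozenset(genes))
    raise InputError(f"unknown merge rule {merge!r}")


def _check_same_regulator(peaksets: list[PeakSet]) -> None:
    if not peaksets:
        raise InputError("need at least one peakset")
    regs = {ps.regulator for ps in peaksets}
    if len(regs) > 1:
        raise InputError(f"mixed regulators in merge: {sorted(regs)}")


# ---------------------------------------------------------------------------
# File formats

def read_bed(path, regulator: str | None = None, source: str | None = None) -> PeakSet:
    """Read a BED3+ peak file (0-based half-open)."""
    path = Path(path)
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise InputError(f"{path}:{lineno}: BED line has <3 fields")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise InputError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start < 0 or start >= end:
                raise InputError(f"{path}:{lineno}: invalid interval [{start}, {end})")
            peaks.append(Peak(fields[0], start, end))
    return PeakSet(
        regulator=regulator or path.stem,
        source=source or str(path.name),
        peaks=peaks,
    )


def write_bed(peakset: PeakSet, path) -> None:
    with open(path, "w") as fh:
        for p in peakset.peaks:
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{peakset.regulator}\n")


def read_tss(path, fmt: str = "bed") -> TSSAnnotation:
    """Read TSS annotations from BED6 or GFF3.

    BED: the TSS is ``start`` on '+' and ``end - 1`` on '-' (half-open →
    last covered base).  GFF3 (1-based inclusive): TSS = ``start`` on '+'
    and ``end`` on '-'; both converted to 0-based coordinates internally.
    """
    fmt = fmt.lower()
    if fmt not in ("bed", "gff3"):
        raise InputError(f"unknown TSS format {fmt!r}")
    ann = TSSAnnotation()
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            try:
                if fmt == "bed":
                    if len(fields) < 6:
                        raise InputError(
                            f"{path}:{lineno}: BED TSS annotation needs 6 fields"
                        )
                    chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                    gene, strand = fields[3], fields[5]
                    pos = start if strand == "+" else end - 1
                else:
                    if len(fields) < 9:
                        raise InputError(f"{path}:{lineno}: GFF3 line has <9 fields")
                    if fields[2] not in ("gene", "transcript", "mRNA"):
                        continue
                    chrom, start, end = fields[0], int(fields[3]), int(fields[4])
                    strand = fields[6]
                    gene = _gff3_gene_id(fields[8], path, lineno)
                    # 1-based inclusive -> 0-based coordinate of the TSS base
                    pos = start - 1 if strand == "+" else end - 1
                ann.add(gene, chrom, pos, strand)
            except (ValueError, IndexError) as exc:
                raise InputError(f"{path}:{lineno}: malformed line") from exc
    return ann


def _gff3_gene_id(attributes: str, path, lineno: int) -> str:
    attrs = {}
    for part in attributes.split(";"):
        if "=" in part:
            key, val = part.split("=", 1)
            attrs[key.strip()] = val.strip()
    for key in ("gene_id", "Name", "ID"):
        if key in attrs:
            return attrs[key]
    raise InputError(f"{path}:{lineno}: no gene identifier in GFF3 attributes")


def write_gmt(signatures: list[TFSignature], path, description: str = "") -> None:
    """Write signatures as GMT (name, description, tab-separated genes)."""
    with open(path, "w") as fh:
        for sig in signatures:
            genes = "\t".join(sorted(sig.genes))
            fh.write(f"{sig.regulator}\t{description}\t{genes}\n")
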