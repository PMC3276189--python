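"""Readers and writers for the standard formats the pipeline touches.

VCF is handled with pysam, GFF3 with gffutils, FASTA with pyfaidx. All
internal coordinates are 0-based half-open; VCF and GFF3 surfaces stay
1-based. Tab-separated outputs carry a header line beginning ``#``.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Tuple, Union

import gffutils
import pysam
from pyfaidx import Fasta

from .model import (
    Genotype,
    GeneModel,
    KnownSiteIndex,
    MappedInterval,
    MultiplexCallSet,
    MultiplexSite,
    PedGenotype,
    PedigreeRecord,
    Phenotype,
    Role,
    SampleCall,
    VariantSite,
)

log = logging.getLogger(__name__)

_DNA = frozenset("ACGT")

PathLike = Union[str, Path]


class ReferenceSequence:
    """In-memory reference accessor addressed by absolute coordinates.

    A contig may be a sub-region of a larger chromosome: FASTA headers of
    the samtools-faidx form ``chr1:45000001-45400000`` are interpreted as
    the 1-based inclusive slice of ``chr1``, so lookups still use absolute
    chromosome coordinates.
    """

    def __init__(
        self,
        sequences: Mapping[str, str],
        offsets: Optional[Mapping[str, int]] = None,
    ) -> None:
        self._seq = {k: v.upper() for k, v in sequences.items()}
        self._off = dict(offsets or {})

    @classmethod
    def from_fasta(cls, path: PathLike) -> "ReferenceSequence":
        fa = Fasta(str(path), as_raw=True, rebuild=True)
        seqs: dict[str, str] = {}
        offs: dict[str, int] = {}
        for name in fa.keys():
            chrom, off = _parse_region_name(name)
            seqs[chrom] = str(fa[name][:])
            if off:
                offs[chrom] = off
        fa.close()
        return cls(seqs, offs)

    def contigs(self) -> list[str]:
        return sorted(self._seq)

    def offset(self, chrom: str) -> int:
        return self._off.get(chrom, 0)

    def length(self, chrom: str) -> int:
        """Absolute end coordinate of the stored slice."""
        return self.offset(chrom) + len(self._seq[chrom])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Sequence for [start, end), 0-based half-open absolute coordinates."""
        off = self.offset(chrom)
        s, e = start - off, end - off
        if s < 0 or e > len(self._seq[chrom]):
            raise KeyError(
                f"{chrom}:{start}-{end} outside stored reference slice"
            )
        return self._seq[chrom][s:e]

    def base(self, chrom: str, pos0: int) -> str:
        return self.fetch(chrom, pos0, pos0 + 1)


def _parse_region_name(name: str) -> Tuple[str, int]:
    if ":" in name:
        chrom, _, span = name.partition(":")
        a, _, b = span.partition("-")
        if a.isdigit() and b.isdigit():
            return chrom, int(a) - 1
    return name, 0


def write_fasta(ref: ReferenceSequence, path: PathLike, width: int = 60) -> None:
    with open(path, "w") as fh:
        for chrom in ref.contigs():
            off = ref.offset(chrom)
            seq = ref.fetch(chrom, off, ref.length(chrom))
            name = chrom if off == 0 else f"{chrom}:{off + 1}-{off + len(seq)}"
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Multiplex VCF
# ---------------------------------------------------------------------------

_ROLE_ORDER = list(Role)


def read_variant_calls(
    path: PathLike, role_map: Mapping[str, Union[Role, str]], line_id: str = ""
) -> MultiplexCallSet:
    """Read a six-sample VCF into a :class:`MultiplexCallSet`.

    ``role_map`` maps VCF sample names to roles and must cover the six
    roles exactly once. Multi-allelic records are split into biallelic SNV
    records; non-SNV alleles are dropped with a warning. A missing GT or a
    zero/missing DP forces NO_CALL (depth defaults to 0 when DP is absent).
    """
    roles = {s: Role(r) for s, r in role_map.items()}
    seen = list(roles.values())
    if sorted(set(seen), key=_ROLE_ORDER.index) != _ROLE_ORDER or len(seen) != 6:
        raise ValueError("role_map must assign each of the six roles exactly once")

    sites: list[MultiplexSite] = []
    with pysam.VariantFile(str(path)) as vcf:
        header_samples = set(vcf.header.samples)
        missing = sorted(set(roles) - header_samples)
        if missing:
            raise ValueError(f"samples in role_map absent from VCF header: {missing}")
        for rec in vcf:
            if rec.alts is None:
                continue
            for alt in rec.alts:
                if len(rec.ref) != 1 or len(alt) != 1 or alt not in _DNA or rec.ref not in _DNA:
                    log.warning(
                        "skipping non-SNV allele %s>%s at %s:%d",
                        rec.ref, alt, rec.chrom, rec.pos,
                    )
                    continue
                site = VariantSite(rec.chrom, rec.pos, rec.ref, alt)
                alt_index = rec.alleles.index(alt)
                calls = {}
                for sample_id, role in roles.items():
                    s = rec.samples[sample_id]
                    gt = s.get("GT")
                    dp = s.get("DP")
                    depth = int(dp) if dp is not None else 0
                    if gt is None or any(a is None for a in gt) or depth < 1:
                        geno = Genotype.NO_CALL
                    else:
                        copies = sum(1 for a in gt if a == alt_index)
                        geno = {0: Genotype.HOM_REF, 1: Genotype.HET, 2: Genotype.HOM_ALT}[
                            copies
                        ]
                    calls[role] = SampleCall(sample_id, role, geno, depth)
                sites.append(MultiplexSite(site, calls))
    return MultiplexCallSet(line_id, sites)


_GT_CODE = {
    Genotype.HOM_REF: (0, 0),
    Genotype.HET: (0, 1),
    Genotype.HOM_ALT: (1, 1),
    Genotype.NO_CALL: (None, None),
}


def write_variant_calls(
    callset: MultiplexCallSet,
    path: PathLike,
    contig_lengths: Optional[Mapping[str, int]] = None,
) -> None:
    """Write a :class:`MultiplexCallSet` as an uncompressed six-sample VCF."""
    header = pysam.VariantHeader()
    header.add_meta("source", "enuscan")
    lengths: dict[str, int] = dict(contig_lengths or {})
    for s in callset.sites:
        need = s.site.pos + 1000
        if lengths.get(s.site.chrom, 0) < need:
            lengths.setdefault(s.site.chrom, need)
            lengths[s.site.chrom] = max(lengths[s.site.chrom], need)
    for chrom in sorted(lengths):
        header.contigs.add(chrom, length=lengths[chrom])
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("DP", 1, "Integer", "Read depth")
    sample_ids = callset.sample_ids()
    ordered = [sample_ids.get(r, r.value.lower()) for r in _ROLE_ORDER]
    for sid in ordered:
        header.add_sample(sid)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for s in sorted(callset.sites, key=lambda x: x.site.key):
            rec = out.new_record(
                contig=s.site.chrom,
                start=s.site.pos - 1,
                alleles=(s.site.ref_allele, s.site.alt_allele),
            )
            for role, sid in zip(_ROLE_ORDER, ordered):
                call = s.calls[role]
                rec.samples[sid]["GT"] = _GT_CODE[call.genotype]
                rec.samples[sid]["DP"] = call.depth
            out.write(rec)


def read_roles(path: PathLike) -> dict[str, Role]:
    roles: dict[str, Role] = {}
    for line in _data_lines(path):
        sample_id, role = line.split("\t")[:2]
        roles[sample_id] = Role(role)
    return roles


def write_roles(sample_ids: Mapping[Role, str], path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("#sample_id\trole\n")
        for role in _ROLE_ORDER:
            fh.write(f"{sample_ids[role]}\t{role.value}\n")


# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------


def read_gene_models(path: PathLike, dialect: Optional[str] = None) -> list[GeneModel]:
    """Read transcript models from BED12 or GFF3.

    The dialect is auto-detected from the extension (override with
    ``dialect='bed12'`` or ``'gff3'``). Coordinates are normalized to
    0-based half-open.
    """
    if dialect is None:
        suffix = Path(path).suffix.lower()
        dialect = "bed12" if suffix == ".bed" else "gff3"
    if dialect == "bed12":
        return _read_bed12(path)
    if dialect == "gff3":
        return _read_gff3(path)
    raise ValueError(f"unknown gene-model dialect {dialect!r}")


def _read_bed12(path: PathLike) -> list[GeneModel]:
    models = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ValueError(f"{path}:{lineno}: BED12 requires 12 fields")
            chrom, start, end = f[0], int(f[1]), int(f[2])
            name, strand = f[3], f[5]
            thick_start, thick_end = int(f[6]), int(f[7])
            count = int(f[9])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            if len(sizes) != count or len(starts) != count:
                raise ValueError(f"{path}:{lineno}: block count mismatch")
            exons = []
            for off, size in zip(starts, sizes):
                ex = (start + off, start + off + size)
                if ex[0] < start or ex[1] > end:
                    raise ValueError(
                        f"{path}:{lineno}: exon {ex} outside transcript bounds"
                    )
                exons.append(ex)
            gene_id, _, tx_id = name.partition("|")
            if thick_start >= thick_end:  # non-coding
                thick_start = thick_end = start
            models.append(
                GeneModel(
                    gene_id=gene_id,
                    transcript_id=tx_id or name,
                    chrom=chrom,
                    strand=strand,
                    exons=tuple(exons),
                    cds_start=thick_start,
                    cds_end=thick_end,
                )
            )
    return models


def _read_gff3(path: PathLike) -> list[GeneModel]:
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    models = []
    for tx in db.all_features(order_by=("seqid", "start")):
        if tx.featuretype not in ("mRNA", "transcript"):
            continue
        exons = sorted(
            (e.start - 1, e.end) for e in db.children(tx, featuretype="exon")
        )
        if not exons:
            raise ValueError(f"transcript {tx.id} has no exons")
        cds = [(c.start - 1, c.end) for c in db.children(tx, featuretype="CDS")]
        if cds:
            cds_start = min(c[0] for c in cds)
            cds_end = max(c[1] for c in cds)
        else:
            cds_start = cds_end = exons[0][0]
        for ex in exons:
            if ex[0] < tx.start - 1 or ex[1] > tx.end:
                raise ValueError(
                    f"transcript {tx.id}: exon {ex} outside transcript bounds"
                )
        gene_id = tx.attributes.get("Parent", [tx.id])[0]
        models.append(
            GeneModel(
                gene_id=gene_id.removeprefix("gene:"),
                transcript_id=tx.id.removeprefix("transcript:"),
                chrom=tx.seqid,
                strand=tx.strand,
                exons=tuple(exons),
                cds_start=cds_start,
                cds_end=cds_end,
            )
        )
    return models


def write_gene_models_gff3(models: Sequence[GeneModel], path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        by_gene: dict[str, list[GeneModel]] = {}
        for m in models:
            by_gene.setdefault(m.gene_id, []).append(m)
        for gene_id in sorted(by_gene):
            txs = by_gene[gene_id]
            g_start = min(t.tx_start for t in txs)
            g_end = max(t.tx_end for t in txs)
            chrom, strand = txs[0].chrom, txs[0].strand
            fh.write(
                f"{chrom}\tenuscan\tgene\t{g_start + 1}\t{g_end}\t.\t{strand}\t.\t"
                f"ID=gene:{gene_id}\n"
            )
            for t in sorted(txs, key=lambda t: t.transcript_id):
                fh.write(
                    f"{t.chrom}\tenuscan\tmRNA\t{t.tx_start + 1}\t{t.tx_end}\t.\t"
                    f"{t.strand}\t.\tID={t.transcript_id};Parent=gene:{gene_id}\n"
                )
                for s, e in t.exons:
                    fh.write(
                        f"{t.chrom}\tenuscan\texon\t{s + 1}\t{e}\t.\t{t.strand}\t.\t"
                        f"Parent={t.transcript_id}\n"
                    )
                if t.is_coding:
                    for s, e in t.cds_intervals():
                        fh.write(
                            f"{t.chrom}\tenuscan\tCDS\t{s + 1}\t{e}\t.\t{t.strand}\t"
                            f"0\tParent={t.transcript_id}\n"
                        )


def write_gene_models_bed12(models: Sequence[GeneModel], path: PathLike) -> None:
    with open(path, "w") as fh:
        for m in sorted(models, key=lambda m: (m.chrom, m.tx_start, m.transcript_id)):
            start, end = m.tx_start, m.tx_end
            sizes = ",".join(str(e - s) for s, e in m.exons) + ","
            starts = ",".join(str(s - start) for s, e in m.exons) + ","
            thick_start, thick_end = (
                (m.cds_start, m.cds_end) if m.is_coding else (start, start)
            )
            name = f"{m.gene_id}|{m.transcript_id}"
            fh.write(
                f"{m.chrom}\t{start}\t{end}\t{name}\t0\t{m.strand}\t"
                f"{thick_start}\t{thick_end}\t0\t{len(m.exons)}\t{sizes}\t{starts}\n"
            )


# ---------------------------------------------------------------------------
# Known sites, intervals, pedigree
# ---------------------------------------------------------------------------


def read_known_sites(path: PathLike, dialect: Optional[str] = None) -> KnownSiteIndex:
    """Read a known-polymorphism catalog from VCF or 3-column TSV.

    Non-SNV records are skipped with a warning; duplicate keys collapse.
    """
    if dialect is None:
        dialect = "vcf" if Path(path).suffix.lower() == ".vcf" else "tsv"
    index = KnownSiteIndex()
    if dialect == "vcf":
        with pysam.VariantFile(str(path)) as vcf:
            for rec in vcf:
                for alt in rec.alts or ():
                    if len(rec.ref) != 1 or len(alt) != 1 or alt not in _DNA:
                        log.warning(
                            "known-sites: skipping non-SNV %s>%s at %s:%d",
                            rec.ref, alt, rec.chrom, rec.pos,
                        )
                        continue
                    index.add(rec.chrom, rec.pos, alt)
    else:
        for line in _data_lines(path):
            chrom, pos, alt = line.split("\t")[:3]
            if len(alt) != 1 or alt not in _DNA:
                log.warning("known-sites: skipping non-SNV alt %r at %s:%s", alt, chrom, pos)
                continue
            index.add(chrom, int(pos), alt)
    return index


def write_known_sites_tsv(index: KnownSiteIndex, path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("#chrom\tpos\talt\n")
        for chrom, pos, alt in index:
            fh.write(f"{chrom}\t{pos}\t{alt}\n")


def read_mapped_interval(path: PathLike) -> MappedInterval:
    for line in _data_lines(path):
        f = line.split("\t")
        chrom, start, end = f[0], int(f[1]), int(f[2])
        prox = dist = None
        if len(f) > 3 and f[3] not in (".", ""):
            prox, _, dist = f[3].partition("|")
            prox = prox or None
            dist = dist or None
        return MappedInterval(chrom, start, end, prox, dist)
    raise ValueError(f"no interval record in {path}")


def write_mapped_interval(interval: MappedInterval, path: PathLike) -> None:
    name = f"{interval.proximal_marker or ''}|{interval.distal_marker or ''}"
    if name == "|":
        name = "."
    with open(path, "w") as fh:
        fh.write(f"{interval.chrom}\t{interval.start}\t{interval.end}\t{name}\n")


def read_pedigree(path: PathLike) -> list[PedigreeRecord]:
    records = []
    for line in _data_lines(path):
        embryo_id, litter_id, phenotype, genotype = line.split("\t")[:4]
        records.append(
            PedigreeRecord(
                embryo_id, litter_id, Phenotype(phenotype), PedGenotype(genotype)
            )
        )
    return records


def write_pedigree(records: Iterable[PedigreeRecord], path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("#embryo_id\tlitter_id\tphenotype\tgenotype\n")
        for r in records:
            fh.write(
                f"{r.embryo_id}\t{r.litter_id}\t{r.phenotype.value}\t{r.genotype.value}\n"
            )


def _data_lines(path: PathLike) -> Iterable[str]:
    with open(path) as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if line and not line.startswith("#"):
                yield line
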