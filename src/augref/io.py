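"""File-format interchange: FASTA, VCF 4.2, BED, GFA 1.0, UCSC chain, TSV.

Internally everything is 0-based half-open; the writers and readers here
convert to the 1-based conventions of VCF, GFA P-lines and chain files.
VCF parsing is delegated to pysam.
"""

from __future__ import annotations

import os

import numpy as np
import pysam
from pyfaidx import Fasta

from .coords import ChainMap
from .graphbuild import HaplotypeIndex, VariationGraph
from .mapper import AlignmentRecord
from .readsim import SimulatedRead
from .synthpop import ReferenceSequence, Variant, VariantPanel

# ---------------------------------------------------------------------------
# FASTA


def write_fasta(ref: ReferenceSequence, path: str, width: int = 60) -> None:
    with open(path, "w") as fh:
        fh.write(f">{ref.name}\n")
        for i in range(0, ref.length, width):
            fh.write(ref.sequence[i : i + width] + "\n")


def read_fasta(path: str, name: str | None = None) -> ReferenceSequence:
    fa = Fasta(path, sequence_always_upper=True)
    key = name if name is not None else list(fa.keys())[0]
    return ReferenceSequence(key, str(fa[key][:]))


# ---------------------------------------------------------------------------
# VCF


def write_vcf(panel: VariantPanel, path: str, ref: ReferenceSequence | None = None) -> None:
    """Write the panel as a VCF 4.2 with phased GT columns."""
    lines = ["##fileformat=VCFv4.2"]
    length = panel.ref_length or (ref.length if ref else None)
    if length:
        lines.append(f"##contig=<ID={panel.chrom},length={length}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for sid, pop in panel.samples:
        lines.append(f"##SAMPLE=<ID={sid},Population={pop}>")
    header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
    header += [sid for sid, _ in panel.samples]
    lines.append("\t".join(header))
    H = panel.haplotypes
    for j, v in enumerate(panel.variants):
        gts = [f"{H[2 * i, j]}|{H[2 * i + 1, j]}" for i in range(len(panel.samples))]
        lines.append(
            "\t".join(
                [panel.chrom, str(v.pos + 1), ".", v.ref, v.alt, ".", "PASS", ".", "GT"]
                + gts
            )
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_vcf(path: str, populations: dict[str, str] | None = None) -> VariantPanel:
    """Read a phased biallelic VCF into a panel (population labels from
    ##SAMPLE header lines, a mapping argument, or 'pop0' fallback)."""
    pops: dict[str, str] = dict(populations or {})
    ref_length = None
    chrom = None
    with open(path) as fh:
        for line in fh:
            if not line.startswith("##"):
                break
            if line.startswith("##SAMPLE=<"):
                body = line.strip()[10:-1]
                fields = dict(kv.split("=", 1) for kv in body.split(","))
                if "ID" in fields and "Population" in fields:
                    pops.setdefault(fields["ID"], fields["Population"])
            if line.startswith("##contig=<"):
                body = line.strip()[10:-1]
                fields = dict(kv.split("=", 1) for kv in body.split(","))
                ref_length = int(fields.get("length", 0)) or None
    vf = pysam.VariantFile(path)
    sample_ids = list(vf.header.samples)
    samples = [(sid, pops.get(sid, "pop0")) for sid in sample_ids]
    variants: list[Variant] = []
    columns: list[np.ndarray] = []
    for rec in vf:
        if len(rec.alts or ()) != 1:
            raise ValueError(f"only biallelic records supported (pos {rec.pos})")
        chrom = rec.chrom
        variants.append(Variant(rec.chrom, rec.start, rec.ref, rec.alts[0]))
        col = np.zeros(2 * len(sample_ids), dtype=np.int8)
        for i, sid in enumerate(sample_ids):
            gt = rec.samples[sid]["GT"]
            col[2 * i] = gt[0] or 0
            col[2 * i + 1] = (gt[1] if len(gt) > 1 else gt[0]) or 0
        columns.append(col)
    H = (
        np.stack(columns, axis=1)
        if columns
        else np.zeros((2 * len(sample_ids), 0), dtype=np.int8)
    )
    return VariantPanel(variants, samples, H, ref_length=ref_length,
                        chrom=chrom or "chrS")


# ---------------------------------------------------------------------------
# BED


def write_bed(features: list[tuple[int, int, str]], chrom: str, path: str) -> None:
    with open(path, "w") as fh:
        for start, end, label in features:
            fh.write(f"{chrom}\t{start}\t{end}\t{label}\n")


def read_bed(path: str) -> list[tuple[int, int, str]]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            out.append((int(f[1]), int(f[2]), f[3] if len(f) > 3 else "region"))
    return out


# ---------------------------------------------------------------------------
# GFA 1.0


def write_gfa(
    graph: VariationGraph, path: str, hapindex: HaplotypeIndex | None = None
) -> None:
    """Serialize the graph as GFA 1.0 with P-lines for backbone and walks."""
    with open(path, "w") as fh:
        fh.write("H\tVN:Z:1.0\n")
        for nid in sorted(graph.nodes):
            fh.write(f"S\t{nid}\t{graph.nodes[nid]}\n")
        for u, v in sorted(graph.edges):
            fh.write(f"L\t{u}\t+\t{v}\t+\t0M\n")
        backbone = ",".join(f"{n}+" for n in graph.backbone)
        fh.write(f"P\t{graph.ref_name}\t{backbone}\t*\n")
        if hapindex:
            for (sid, hap), walk in sorted(hapindex.walks.items()):
                fh.write(f"P\t{sid}_h{hap}\t{','.join(f'{n}+' for n in walk)}\t*\n")


# ---------------------------------------------------------------------------
# UCSC chain


def write_chain(chain: ChainMap, path: str, src_name: str, tgt_name: str) -> None:
    """Write the map as a single forward-strand UCSC chain."""
    with open(path, "w") as fh:
        if not chain.blocks:
            return
        s0 = chain.blocks[0][0]
        t0 = chain.blocks[0][1]
        s_end = chain.blocks[-1][0] + chain.blocks[-1][2]
        t_end = chain.blocks[-1][1] + chain.blocks[-1][2]
        fh.write(
            f"chain 1000 {src_name} {chain.src_len} + {s0} {s_end} "
            f"{tgt_name} {chain.tgt_len} + {t0} {t_end} 1\n"
        )
        for i, (s, t, ln) in enumerate(chain.blocks):
            if i + 1 < len(chain.blocks):
                ns, nt, _ = chain.blocks[i + 1]
                fh.write(f"{ln}\t{ns - (s + ln)}\t{nt - (t + ln)}\n")
            else:
                fh.write(f"{ln}\n")
        fh.write("\n")


def read_chain(path: str) -> ChainMap:
    blocks = []
    with open(path) as fh:
        header = None
        s = t = 0
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if parts[0] == "chain":
                header = parts
                s, t = int(parts[5]), int(parts[10])
                src_len, tgt_len = int(parts[3]), int(parts[8])
                continue
            ln = int(parts[0])
            blocks.append((s, t, ln))
            if len(parts) == 3:
                s += ln + int(parts[1])
                t += ln + int(parts[2])
    if header is None:
        raise ValueError("no chain record found")
    return ChainMap(blocks, src_len, tgt_len)


# ---------------------------------------------------------------------------
# reads and alignments


def write_fastq(reads: list[SimulatedRead], path: str, qual_char: str = "I") -> None:
    """FASTQ with truth-encoding names:
    ``id/mate sample hap true_start strand nonref``."""
    with open(path, "w") as fh:
        for r in reads:
            name = (
                f"@{r.id}/{r.mate} {r.sample} h{r.hap} {r.true_ref_start} "
                f"{r.strand} {'N' if r.contains_nonref else 'R'}"
            )
            fh.write(f"{name}\n{r.sequence}\n+\n{qual_char * len(r.sequence)}\n")


def write_truth_table(reads: list[SimulatedRead], path: str) -> None:
    with open(path, "w") as fh:
        fh.write(
            "read_id\tmate\tsample\thap\ttrue_ref_start\ttrue_ref_end\t"
            "strand\tfrag_len\tcontains_nonref\tregions\n"
        )
        for r in reads:
            fh.write(
                f"{r.id}\t{r.mate}\t{r.sample}\t{r.hap}\t{r.true_ref_start}\t"
                f"{r.true_ref_end}\t{r.strand}\t{r.frag_len}\t"
                f"{int(bool(r.contains_nonref))}\t"
                f"{','.join(sorted(r.region_labels)) or '.'}\n"
            )


def write_alignments_tsv(alignments: list[AlignmentRecord], path: str) -> None:
    """SAM-like TSV (1-based ref_pos on output, as in SAM)."""
    with open(path, "w") as fh:
        fh.write("read_id\tmate\tmapped\tref_pos\tstrand\tmq\tNM\tsoft_clip\t"
                 "n_secondary\tscore\n")
        for a in alignments:
            pos = a.ref_pos + 1 if a.mapped else 0
            fh.write(
                f"{a.read_id}\t{a.mate}\t{int(a.mapped)}\t{pos}\t{a.strand}\t"
                f"{a.mq}\t{a.edit_distance}\t{a.soft_clip}\t{a.n_secondary}\t"
                f"{a.score:g}\n"
            )


def write_calls_vcf(calls, ref: ReferenceSequence, path: str,
                    emit_homref: bool = False) -> None:
    """Genotype calls as single-sample VCF 4.2 with GT:AD:DP plus MQ/QD."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={ref.name},length={ref.length}>\n")
        fh.write('##INFO=<ID=QD,Number=1,Type=Float,Description="Qual by depth">\n')
        fh.write('##INFO=<ID=MQ,Number=1,Type=Float,Description="Mean mapping qual">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depth">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tsample\n")
        for c in calls:
            if c.genotype == "0/0" and not emit_homref:
                continue
            v = c.site.variant
            info = f"QD={c.qd:.2f};MQ={c.site.mean_mq:.1f}"
            fh.write(
                f"{v.chrom}\t{v.pos + 1}\t.\t{v.ref}\t{v.alt}\t{c.qual:.1f}\t"
                f"{c.filter_status}\t{info}\tGT:AD:DP\t"
                f"{c.genotype}:{c.site.ad_ref},{c.site.ad_alt}:{c.site.dp}\n"
            )


def ensure_dir(path: str) -> str:
    os.makedirs(path, exist_ok=True)
    return path
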