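"""Reading and writing polarized phased VCFs.

Simulator output is written as VCF 4.2 with the derived allele as ALT and
the ancestral allele recorded in the AA INFO tag.  External VCFs are
polarized on input: sites are re-oriented so that the matrix codes derived
alleles, using either the AA tag or a position -> ancestral-allele table.
Internal coordinates are 0-based half-open; the 1-based conversion lives
entirely in this module.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pysam

from .sample import HaplotypeSample

__all__ = ["write_vcf", "read_polarized_variants", "read_ancestral_table"]

log = logging.getLogger(__name__)

_CONTIG = "1"


def write_vcf(sample: HaplotypeSample, path, metadata: dict | None = None) -> Path:
    """Write a sample as a phased diploid VCF (ALT = derived, AA = ancestral).

    An optional sidecar JSON (``<path>.json``) records provenance metadata.
    """
    path = Path(path)
    if sample.n_hap % 2 != 0:
        raise ValueError("need an even number of haplotypes for diploid output")
    n_ind = sample.n_hap // 2
    names = [f"ind{i}" for i in range(n_ind)]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={_CONTIG},length={sample.sequence_length}>\n")
        fh.write('##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(names) + "\n")
        G = sample.genotypes
        for s in range(sample.n_sites):
            gts = "\t".join(
                f"{G[s, 2 * i]}|{G[s, 2 * i + 1]}" for i in range(n_ind)
            )
            fh.write(
                f"{_CONTIG}\t{sample.positions[s] + 1}\t.\tA\tT\t.\t.\tAA=A\tGT\t{gts}\n"
            )
    if metadata is not None:
        meta = dict(metadata)
        meta.setdefault("generation", sample.generation)
        meta.setdefault("scenario_tag", sample.scenario_tag)
        meta.setdefault("sequence_length", sample.sequence_length)
        Path(str(path) + ".json").write_text(json.dumps(meta, indent=2))
    return path


def read_ancestral_table(path) -> dict[int, str]:
    """Read a two-column ``position<TAB>ancestral-allele`` table (1-based)."""
    table: dict[int, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        pos, allele = line.split()[:2]
        table[int(pos)] = allele.upper()
    return table


def read_polarized_variants(
    vcf_path,
    ancestral: str | dict[int, str] = "AA",
    sequence_length: int | None = None,
    generation: int | None = None,
    scenario_tag: str = "",
) -> HaplotypeSample:
    """Read a phased diploid VCF into a derived-allele haplotype sample.

    ``ancestral`` is either ``"AA"`` (use the AA INFO tag), the path of an
    ancestral-allele table, or an already-loaded ``{1-based pos: allele}``
    mapping.  Multiallelic sites, sites without a usable ancestral
    annotation (or whose annotation matches neither allele), and sites
    monomorphic in the sample are dropped (with a logged count); unphased
    genotypes raise an error.
    """
    vcf_path = Path(vcf_path)
    if not vcf_path.exists():
        raise FileNotFoundError(vcf_path)
    table: dict[int, str] | None = None
    if isinstance(ancestral, dict):
        table = ancestral
    elif ancestral != "AA":
        table = read_ancestral_table(ancestral)

    positions: list[int] = []
    rows: list[np.ndarray] = []
    n_multi = n_no_aa = n_mono = 0
    with pysam.VariantFile(str(vcf_path)) as vf:
        if sequence_length is None:
            contigs = list(vf.header.contigs.values())
            if contigs and contigs[0].length:
                sequence_length = contigs[0].length
        for rec in vf:
            if rec.alts is None or len(rec.alts) != 1:
                n_multi += 1
                continue
            ref, alt = rec.ref.upper(), rec.alts[0].upper()
            if table is not None:
                aa = table.get(rec.pos)
            else:
                aa = rec.info.get("AA")
                if isinstance(aa, (tuple, list)):
                    aa = aa[0]
                aa = aa.upper() if isinstance(aa, str) else None
            if aa is None or aa not in (ref, alt):
                n_no_aa += 1
                continue
            hap = []
            for sm in rec.samples.values():
                gt = sm["GT"]
                if gt is None or len(gt) != 2 or any(a is None for a in gt):
                    raise ValueError(f"missing or non-diploid genotype at pos {rec.pos}")
                if not sm.phased:
                    raise ValueError(f"unphased genotype at pos {rec.pos}")
                hap.extend(gt)
            hap = np.asarray(hap, dtype=np.uint8)
            if aa == alt:  # the ALT allele is ancestral: flip to derived coding
                hap = 1 - hap
            c = int(hap.sum())
            if c == 0 or c == hap.size:
                n_mono += 1
                continue
            positions.append(rec.pos - 1)
            rows.append(hap)

    dropped = n_multi + n_no_aa + n_mono
    if dropped:
        log.info(
            "dropped %d sites (%d multiallelic, %d without ancestral annotation, "
            "%d monomorphic in sample)",
            dropped, n_multi, n_no_aa, n_mono,
        )
    if rows:
        G = np.stack(rows)
        pos = np.asarray(positions, dtype=np.int64)
        order = np.argsort(pos, kind="stable")
        pos, G = pos[order], G[order]
        if sequence_length is None:
            sequence_length = int(pos[-1]) + 1
    else:
        G = np.zeros((0, 0), dtype=np.uint8)
        pos = np.zeros(0, dtype=np.int64)
        sequence_length = sequence_length or 1
    return HaplotypeSample(
        positions=pos,
        genotypes=G,
        sequence_length=int(sequence_length),
        generation=generation,
        scenario_tag=scenario_tag,
    )
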