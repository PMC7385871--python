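"""Major-allele consensus linear references.

Replaces every reference allele whose alternate allele frequency in a
population strictly exceeds 0.5 with the alternate allele (ties retain
the reference), optionally restricted to SNPs so the coordinate system
is preserved. The accompanying :class:`~augref.coords.ChainMap` records
all indel-induced coordinate shifts and can be serialized as a UCSC
chain file by :mod:`augref.io`.
"""

from __future__ import annotations

from .coords import ChainMap, apply_alleles
from .synthpop import ReferenceSequence, Variant, VariantPanel

__all__ = ["build_consensus", "replaced_sites"]


def replaced_sites(
    panel: VariantPanel, pop: str | None, snp_only: bool = False
) -> list[Variant]:
    """Variants whose alternate allele is the population's major allele."""
    af = panel.af(pop)
    out = []
    for v, f in zip(panel.variants, af):
        if f > 0.5 and (not snp_only or v.vclass == "SNP"):
            out.append(v)
    return out


def build_consensus(
    ref: ReferenceSequence,
    panel: VariantPanel,
    pop: str | None = None,
    snp_only: bool = False,
    name: str | None = None,
) -> tuple[ReferenceSequence, ChainMap, list[Variant]]:
    """Build a major-allele consensus sequence and its coordinate chain.

    Returns (consensus, chain, replaced) where ``chain`` maps original
    reference coordinates (source) to consensus coordinates (target) and
    ``replaced`` lists the substituted sites.
    """
    replaced = replaced_sites(panel, pop, snp_only)
    seq, chain = apply_alleles(ref, replaced)
    label = name or f"{ref.name}_consensus{'_snp' if snp_only else ''}"
    return ReferenceSequence(label, seq, list(ref.features)), chain, replaced
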