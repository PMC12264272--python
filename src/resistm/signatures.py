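"""Gene-signature definitions and the built-in signature registry.

A :class:`GeneSignature` is a named gene set split into two arms by
prognostic direction: ``up_genes`` move *up* in the high-risk phenotype
(they are rank-reflected before being combined with the protective arm),
while ``down_genes`` move *down* and are used as-is.  The registry holds
the nine-gene RESIST-M oxaliplatin-resistance/metastasis signature for
colorectal cancer, its two arms (RESIST-M1: SERPINE1, SMARCD3;
RESIST-M2: seven cholesterol-biosynthesis genes), and four published
comparator signatures (Yin et al., Lin et al., the seven-gene subset of
the colon-cancer recurrence score RCC, and the recombination-proficiency
score RPS).
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["GeneSignature", "builtin_registry", "RESIST_M1_GENES", "RESIST_M2_GENES"]

RESIST_M1_GENES = ("SERPINE1", "SMARCD3")
RESIST_M2_GENES = ("SC5D", "FDPS", "MVD", "HMGCS1", "HMGCR", "CYP51A1", "ACAT2")


@dataclass(frozen=True)
class GeneSignature:
    """A named gene set with per-gene prognostic direction.

    Parameters
    ----------
    name:
        Signature identifier, e.g. ``"RESIST-M"``.
    up_genes:
        Genes elevated in the risk phenotype (reflected before combining).
    down_genes:
        Genes suppressed in the risk phenotype (used unchanged).
    provenance:
        Free-text citation or origin note.
    """

    name: str
    up_genes: tuple[str, ...] = ()
    down_genes: tuple[str, ...] = ()
    provenance: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "up_genes", tuple(self.up_genes))
        object.__setattr__(self, "down_genes", tuple(self.down_genes))
        overlap = set(self.up_genes) & set(self.down_genes)
        if overlap:
            raise ValueError(
                f"signature {self.name!r}: genes in both arms: {sorted(overlap)}"
            )
        if not self.up_genes and not self.down_genes:
            raise ValueError(f"signature {self.name!r} has no genes")

    @property
    def genes(self) -> tuple[str, ...]:
        """All member genes, up-arm first."""
        return self.up_genes + self.down_genes

    def __len__(self) -> int:
        return len(self.up_genes) + len(self.down_genes)


def builtin_registry() -> dict[str, GeneSignature]:
    """Return the built-in signature registry, keyed by signature name.

    Contains RESIST-M1 (risk-up arm), RESIST-M2 (protective
    cholesterol-biosynthesis arm), the combined nine-gene RESIST-M, and
    the comparators Yin, Lin, RCC7 (the seven cancer-related genes of the
    twelve-gene colon-cancer recurrence score, split into stromal/
    GADD45B risk-up and cell-cycle down arms) and RPS (four DNA-repair
    genes).
    """
    sigs = [
        GeneSignature(
            "RESIST-M1",
            up_genes=RESIST_M1_GENES,
            provenance="RESIST-M risk arm, oxaliplatin-resistant HCT116 models",
        ),
        GeneSignature(
            "RESIST-M2",
            down_genes=RESIST_M2_GENES,
            provenance="RESIST-M protective arm, cholesterol biosynthesis",
        ),
        GeneSignature(
            "RESIST-M",
            up_genes=RESIST_M1_GENES,
            down_genes=RESIST_M2_GENES,
            provenance="combined nine-gene RESIST-M signature",
        ),
        GeneSignature(
            "Yin",
            up_genes=("P4HA1", "ATF6", "PHLDB3", "IBTK", "COPE"),
            provenance="Yin et al. oxaliplatin-resistance signature",
        ),
        GeneSignature(
            "Lin",
            up_genes=("ALCAM", "CD22", "CASP1", "CISH"),
            provenance="Lin et al. oxaliplatin-resistance signature",
        ),
        GeneSignature(
            "RCC7",
            up_genes=("INHBA", "BGN", "FAP", "GADD45B"),
            down_genes=("MKI67", "MYC", "MYBL2"),
            provenance="colon-cancer recurrence score, 7 of 12 genes",
        ),
        GeneSignature(
            "RPS",
            up_genes=("RIF1", "XRCC5", "PARPBP", "RAD51"),
            provenance="recombination-proficiency score, 4 DNA-repair genes",
        ),
    ]
    return {s.name: s for s in sigs}
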