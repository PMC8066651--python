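"""Published marginal count tables of the OWB barley F2 teaching population.

Per-individual raw data for that population are not publicly deposited; what
is published are the marginal class counts per trait/marker and the joint
awn-by-marker dissection.  This module packages those counts so the
segregation layer of the analysis can be replicated exactly ("replication
mode"); joint trait-pair tables, and hence the published pairwise linkage
chi-squares, cannot be reconstructed from marginals and are emulated by the
simulator instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

from .segregation import PhenotypeCountTable


@dataclass(frozen=True)
class CountRecord:
    """One published count table with its hypothesised segregation ratio."""

    name: str
    gene: str
    table: PhenotypeCountTable
    ratio: Tuple[float, ...]

    @property
    def key(self) -> str:
        """Stable machine-readable identifier."""
        ratio = "to".join(f"{w:g}" for w in self.ratio)
        slug = self.name.lower().replace(" ", "_").replace("-", "_")
        return f"{slug}_{ratio}"


def _rec(name, gene, labels, counts, ratio) -> CountRecord:
    return CountRecord(
        name, gene, PhenotypeCountTable(tuple(labels), tuple(counts)), tuple(ratio)
    )


def owb_marginal_counts() -> Tuple[CountRecord, ...]:
    """All published marginal count tables, with their tested ratios.

    Morphological traits (dominant vs recessive counts; the awn-type trait is
    additionally tested against 9:7, and awn length is conditional on normal
    awns), the three-class epistatic awn table (9:3:4), the molecular-marker
    class counts, and the four-class awn-by-Knox-dup dissection (9:3:3:1).
    """
    dr = ("dominant", "recessive")
    return (
        _rec("spike_type", "Zeo", dr, (229, 74), (3, 1)),
        _rec("row_number", "Vrs1", dr, (230, 73), (3, 1)),
        _rec("awn_type", "Kap", dr, (169, 133), (3, 1)),
        _rec("awn_type", "Kap", dr, (169, 133), (9, 7)),
        _rec("awn_length", "Lks2", dr, (56, 77), (3, 1)),
        _rec("grain_type", "Nud", dr, (237, 65), (3, 1)),
        _rec("leaf_variegation", "Wst", dr, (237, 66), (3, 1)),
        _rec("stem_pubescence", "Hsh", dr, (186, 70), (3, 1)),
        _rec(
            "awn_three_class",
            "Kap/Lks2",
            ("hooded", "normal-long", "normal-short"),
            (169, 56, 77),
            (9, 3, 4),
        ),
        _rec("Bmac 0310", "Bmac 0310", ("A", "H", "B"), (57, 167, 76), (1, 2, 1)),
        _rec("Bmag 0211", "Bmag 0211", ("A", "H", "B"), (80, 130, 88), (1, 2, 1)),
        _rec("HVM40", "HVM40", ("A", "H", "B"), (63, 160, 78), (1, 2, 1)),
        _rec("Knox-dup", "Knox-dup", ("D", "B"), (230, 73), (3, 1)),
        _rec(
            "awn_by_knox",
            "Kap/Lks2",
            ("D_ Lks2_", "dd Lks2_", "D_ lks2lks2", "dd lks2lks2"),
            (179, 46, 50, 27),
            (9, 3, 3, 1),
        ),
    )
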