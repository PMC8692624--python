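"""Codon accounting under the vertebrate mitochondrial genetic code.

The vertebrate mitochondrial code (NCBI transl_table 2) differs from the
standard code in ways that matter for every statistic here: AGA and AGG are
stop codons, ATA encodes Met and TGA encodes Trp.  Leucine and serine are
reported as the two tRNA families each: Leu1 = CUN, Leu2 = UUR, Ser1 = AGY,
Ser2 = UCN (stop codons AGA/AGG leave Ser1 a two-codon family).

Incomplete stop codons — a terminal T or TA completed to TAA by
polyadenylation of the transcript — are reported as the markers "T-" and
"TA-" and never enter codon counts.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

from Bio.Data import CodonTable

logger = logging.getLogger("mitocompare")

NUCS = "ACGT"


@dataclass(frozen=True)
class GeneticCode:
    """A codon translation table with a synonymous-family partition."""

    table_id: int
    forward: Mapping[str, str]        # codon -> amino-acid label
    stop_codons: frozenset[str]

    def is_stop(self, codon: str) -> bool:
        return codon in self.stop_codons

    def translate(self, codon: str) -> Optional[str]:
        """Amino-acid label for a sense codon, '*' for a stop, None if ambiguous."""
        if codon in self.stop_codons:
            return "*"
        return self.forward.get(codon)

    def family(self, codon: str) -> list[str]:
        """Synonymous family (same label) of a sense codon."""
        aa = self.forward[codon]
        return [c for c, a in self.forward.items() if a == aa]


# two-family split of Leu and Ser following the mitochondrial tRNA set
_SPLIT_LABELS = {
    "TTA": "Leu2", "TTG": "Leu2",
    "CTT": "Leu1", "CTC": "Leu1", "CTA": "Leu1", "CTG": "Leu1",
    "TCT": "Ser2", "TCC": "Ser2", "TCA": "Ser2", "TCG": "Ser2",
    "AGT": "Ser1", "AGC": "Ser1",
}

def vertebrate_mito_code() -> GeneticCode:
    """transl_table 2, with Leu/Ser split into their two tRNA families."""
    return genetic_code(2)


def genetic_code(table_id: int = 2) -> GeneticCode:
    table = CodonTable.unambiguous_dna_by_id[table_id]
    forward: dict[str, str] = {}
    for codon, aa in table.forward_table.items():
        forward[codon] = _SPLIT_LABELS.get(codon, aa) if table_id == 2 else aa
    return GeneticCode(table_id=table_id, forward=forward,
                       stop_codons=frozenset(table.stop_codons))


@dataclass
class CodonCountTable:
    """Pooled sense-codon counts over a set of protein-coding genes."""

    counts: Counter
    aa_totals: Counter
    total: int
    internal_stops: list[tuple[str, int]] = field(default_factory=list)


@dataclass
class RSCUTable:
    """Relative synonymous codon usage per codon.

    RSCU(c) = count(c) * family_size / family_total; 0 with an ``unobserved``
    flag when the whole family has zero counts.
    """

    rscu: dict[str, float]
    family_size: dict[str, int]
    unobserved: set[str]


@dataclass
class StartStopReport:
    gene: str
    start_codon: str
    stop_codon: str          # codon, "T-", "TA-", or "no canonical stop"
    incomplete: bool


def detect_start_stop(cds: str, code: Optional[GeneticCode] = None,
                      gene: str = "") -> StartStopReport:
    """Start and (possibly incomplete) stop codon of an in-frame CDS.

    A CDS whose length is not a multiple of 3 carries an incomplete stop:
    the trailing 1-2 nucleotides are reported as "T-"-style markers.  A
    final full codon outside the stop set is reported as "no canonical
    stop", not raised.
    """
    code = code or vertebrate_mito_code()
    cds = cds.upper()
    if len(cds) < 6:
        raise ValueError(f"{gene or 'CDS'}: too short ({len(cds)} nt)")
    start = cds[:3]
    rem = len(cds) % 3
    if rem:
        return StartStopReport(gene, start, cds[-rem:] + "-", True)
    last = cds[-3:]
    if code.is_stop(last):
        return StartStopReport(gene, start, last, False)
    return StartStopReport(gene, start, "no canonical stop", False)


def iter_codons(cds: str) -> Iterable[str]:
    """Full in-frame codons of a CDS; a trailing partial codon is dropped."""
    cds = cds.upper()
    for i in range(0, len(cds) - len(cds) % 3, 3):
        yield cds[i:i + 3]


def count_codons(cds_by_gene: Mapping[str, str],
                 code: Optional[GeneticCode] = None) -> CodonCountTable:
    """Pool sense-codon counts across genes (stop codons excluded).

    Internal stop codons are tolerated: they are logged with gene and codon
    index, counted as stops and excluded, so a frame-shifted or
    overlap-perturbed gene cannot poison the table.
    """
    code = code or vertebrate_mito_code()
    counts: Counter = Counter()
    internal: list[tuple[str, int]] = []
    for gene, cds in cds_by_gene.items():
        codons = list(iter_codons(cds))
        for idx, codon in enumerate(codons):
            if any(ch not in NUCS for ch in codon):
                continue
            if code.is_stop(codon):
                if idx != len(codons) - 1:
                    internal.append((gene, idx))
                    logger.warning("internal stop %s in %s at codon %d",
                                   codon, gene, idx)
                continue
            counts[codon] += 1
    aa_totals: Counter = Counter()
    for codon, n in counts.items():
        aa_totals[code.forward[codon]] += n
    return CodonCountTable(counts=counts, aa_totals=aa_totals,
                           total=sum(counts.values()), internal_stops=internal)


def rscu(table: CodonCountTable,
         code: Optional[GeneticCode] = None) -> RSCUTable:
    """RSCU over the code's synonymous families.

    Within each family, RSCU(c) = n_c * k / sum(n), k = family size, so the
    family sums to k and uniform usage gives 1.0 everywhere.  Families with
    no observations report 0 for every member, flagged ``unobserved``.
    """
    code = code or vertebrate_mito_code()
    values: dict[str, float] = {}
    fam_size: dict[str, int] = {}
    unobserved: set[str] = set()
    families: dict[str, list[str]] = {}
    for codon, aa in code.forward.items():
        families.setdefault(aa, []).append(codon)
    for aa, fam in families.items():
        k = len(fam)
        tot = sum(table.counts.get(c, 0) for c in fam)
        for c in fam:
            fam_size[c] = k
            if tot == 0:
                values[c] = 0.0
                unobserved.add(c)
            else:
                values[c] = table.counts.get(c, 0) * k / tot
    return RSCUTable(rscu=values, family_size=fam_size, unobserved=unobserved)


def codon_usage_frame(table: CodonCountTable, rscu_table: RSCUTable,
                      code: Optional[GeneticCode] = None):
    """Tidy per-codon DataFrame: codon, amino acid, count, RSCU."""
    import pandas as pd
    code = code or vertebrate_mito_code()
    rows = []
    for codon in sorted(code.forward):
        rows.append({"codon": codon, "aa": code.forward[codon],
                     "count": table.counts.get(codon, 0),
                     "rscu": rscu_table.rscu[codon]})
    return pd.DataFrame(rows)
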