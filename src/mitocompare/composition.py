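"""Base composition, A+T content and strand-asymmetry skews.

AT skew = (A - T)/(A + T) and GC skew = (G - C)/(G + C), computed on the
coding-strand-oriented sequence of each region, so light-strand genes show
inverted skew signs relative to heavy-strand genes.  IUPAC ambiguity codes
and N are excluded from every numerator and denominator.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
import pandas as pd

from .annotation_model import MitoGenome, extract_feature_sequence

logger = logging.getLogger("mitocompare")


@dataclass
class BaseCounts:
    a: int = 0
    c: int = 0
    g: int = 0
    t: int = 0
    other: int = 0

    @property
    def total(self) -> int:
        return self.a + self.c + self.g + self.t + self.other

    @property
    def unambiguous(self) -> int:
        return self.a + self.c + self.g + self.t

    def __add__(self, o: "BaseCounts") -> "BaseCounts":
        return BaseCounts(self.a + o.a, self.c + o.c, self.g + o.g,
                          self.t + o.t, self.other + o.other)


@dataclass
class CompositionStats:
    """A+T% and skews for one labeled region; NaN marks an undefined skew."""
    region: str
    length: int
    at_content: float
    at_skew: float
    gc_skew: float


def base_counts(seq: str) -> BaseCounts:
    """Case-insensitive A/C/G/T tally; U counts as T, everything else as other."""
    if not seq:
        raise ValueError("empty sequence")
    s = seq.upper()
    a, c, g = s.count("A"), s.count("C"), s.count("G")
    t = s.count("T") + s.count("U")
    return BaseCounts(a=a, c=c, g=g, t=t, other=len(s) - a - c - g - t)


def skew_stats(counts: BaseCounts, label: str = "") -> CompositionStats:
    """AT/GC skews and A+T content from base counts.

    A zero A+T (or G+C) pool makes the corresponding skew undefined; it is
    reported as NaN rather than silently as 0.
    """
    if counts.unambiguous == 0:
        raise ValueError(f"{label or 'region'}: no unambiguous bases")
    at, gc = counts.a + counts.t, counts.g + counts.c
    at_skew = (counts.a - counts.t) / at if at else math.nan
    gc_skew = (counts.g - counts.c) / gc if gc else math.nan
    if at == 0 or gc == 0:
        logger.warning("%s: undefined skew (A+T=%d, G+C=%d)", label, at, gc)
    return CompositionStats(region=label, length=counts.total,
                            at_content=100.0 * at / counts.unambiguous,
                            at_skew=at_skew, gc_skew=gc_skew)


_CLASS_LABELS = {"PCG": "PCGs", "tRNA": "tRNAs", "rRNA": "rRNAs", "CR": "CR"}


def region_composition(genome: MitoGenome, grouping: str = "per-gene") -> pd.DataFrame:
    """Composition table for a genome.

    grouping: 'whole' (one row), 'per-gene' (one row per feature, computed on
    the strand-oriented sequence) or 'per-class' (counts pooled over all
    features of each type: PCGs, tRNAs, rRNAs, CR).
    """
    if genome.sequence is None:
        raise ValueError("genome has no sequence")
    rows: list[CompositionStats] = []
    if grouping == "whole":
        rows.append(skew_stats(base_counts(genome.sequence), genome.accession))
    elif grouping == "per-gene":
        for f in genome.features:
            rows.append(skew_stats(
                base_counts(extract_feature_sequence(genome, f)), f.name))
    elif grouping == "per-class":
        for ftype, label in _CLASS_LABELS.items():
            feats = genome.features_of_type(ftype)
            if not feats:
                logger.warning("no %s features; class omitted", ftype)
                continue
            pooled = BaseCounts()
            for f in feats:
                pooled = pooled + base_counts(extract_feature_sequence(genome, f))
            rows.append(skew_stats(pooled, label))
    else:
        raise ValueError(f"unknown grouping {grouping!r}")
    return pd.DataFrame([vars(r) for r in rows])


def composition_table(stats: list[CompositionStats]) -> pd.DataFrame:
    df = pd.DataFrame([vars(s) for s in stats])
    for col in ("at_content", "at_skew", "gc_skew"):
        df[col] = df[col].round(4)
    return df
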