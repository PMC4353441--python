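"""Overlap with, and exclusion of, a variable-gene signature.

Genes whose mammary expression fluctuates across the mouse estrous cycle
confound the interpretation of a radiation response; DE genes matching such
a signature are quantified and removed before downstream analysis.  The
signature is gene-level, DE calls are probe-level: every probe of a
matching gene symbol is removed.  Matching is case-insensitive; probes with
an empty symbol never match.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .io import GeneSet, ProbeAnnotation

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class OverlapResult:
    n_de: int
    n_signature: int
    n_overlap: int
    overlap_fraction: float
    retained: frozenset
    overlapped: frozenset


def overlap_with_signature(de_symbols: GeneSet, signature: GeneSet) -> OverlapResult:
    """Exact set arithmetic between a DE symbol set and a signature.

    The overlap fraction is n_overlap / n_de; an empty DE set reports 0
    with a warning rather than dividing by zero.
    """
    overlapped = de_symbols.symbols & signature.symbols
    retained = de_symbols.symbols - signature.symbols
    n_de = len(de_symbols.symbols)
    if n_de == 0:
        logger.warning("overlap requested for an empty DE set; fraction reported as 0")
        fraction = 0.0
    else:
        fraction = len(overlapped) / n_de
    return OverlapResult(
        n_de=n_de,
        n_signature=len(signature.symbols),
        n_overlap=len(overlapped),
        overlap_fraction=fraction,
        retained=frozenset(retained),
        overlapped=frozenset(overlapped),
    )


def exclude_signature(
    de: pd.DataFrame, ann: ProbeAnnotation, signature: GeneSet
) -> pd.DataFrame:
    """Drop DE-table rows whose gene symbol matches the signature.

    Rows with an empty gene symbol are always retained (absence of evidence
    is not membership).  Idempotent by construction.
    """
    symbols = ann.symbols_for(de.index)
    matches = symbols.isin(signature.symbols) & (symbols != "")
    return de.loc[~matches.to_numpy()]
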