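"""Gene-set over-representation scoring and network-gene selection.

Each gene set is scored on the 2x2 table (DEG-and-in-set, DEG-not-in-set,
set-not-DEG, neither) with a one-sided Fisher exact test (hypergeometric
tail) and a Pearson chi-square test; BH-FDR is computed across all tested
terms.  Gating uses the raw Fisher P.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from coexscreen.diffexpr import DEGTable, bh_adjust
from coexscreen.io import ExpressionMatrix, GeneSetCollection

DEFAULT_P_MAX = 0.01
DEFAULT_N_LNC = 30


@dataclass(frozen=True)
class EnrichmentRecord:
    """One gene set's 2x2 over-representation result."""

    term_id: str
    term_name: str
    a: int  # DEG and in set
    b: int  # DEG, not in set
    c: int  # in set, not DEG
    d: int  # neither
    genes: tuple[str, ...]  # DEG members of the set, sorted
    fisher_p: float
    chisq_p: float
    fdr: float = float("nan")


def _fisher_one_sided(a: int, b: int, c: int, d: int) -> float:
    # over-representation tail: P(X >= a) for X ~ Hypergeom(N=a+b+c+d, K=a+c, n=a+b)
    n_universe = a + b + c + d
    n_set = a + c
    n_deg = a + b
    return float(stats.hypergeom.sf(a - 1, n_universe, n_set, n_deg))


def _chisq_p(a: int, b: int, c: int, d: int, continuity: bool) -> float:
    table = np.array([[a, b], [c, d]], dtype=float)
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        return 1.0
    _, p, _, _ = stats.chi2_contingency(table, correction=continuity)
    return float(p)


def fisher_enrichment(
    deg_ids: Sequence[str],
    universe_ids: Sequence[str],
    sets: GeneSetCollection,
    continuity_correction: bool = False,
) -> list[EnrichmentRecord]:
    """Score every gene set for DEG over-representation within the universe.

    Set members are intersected with the universe before counting; sets with
    no in-universe members are skipped with a warning.  Fisher p is the
    one-sided hypergeometric upper tail; chi-square is Pearson with 1 df,
    without continuity correction unless requested.  The ``fdr`` field is BH
    across all tested terms.
    """
    universe = set(universe_ids)
    if not universe:
        raise ValueError("empty gene universe")
    degs = set(deg_ids)
    stray = degs - universe
    if stray:
        raise ValueError(f"DEG ids outside the universe: {sorted(stray)[:5]}")
    n_universe = len(universe)
    n_deg = len(degs)
    records: list[EnrichmentRecord] = []
    for term_id in sets.sets:
        members = set(sets.members(term_id)) & universe
        if not members:
            warnings.warn(f"gene set {term_id!r} has no members in the universe; skipped")
            continue
        a = len(members & degs)
        b = n_deg - a
        c = len(members) - a
        d = n_universe - a - b - c
        records.append(
            EnrichmentRecord(
                term_id=term_id,
                term_name=sets.term_name(term_id),
                a=a,
                b=b,
                c=c,
                d=d,
                genes=tuple(sorted(members & degs)),
                fisher_p=_fisher_one_sided(a, b, c, d),
                chisq_p=_chisq_p(a, b, c, d, continuity_correction),
            )
        )
    if records:
        fdrs = bh_adjust([r.fisher_p for r in records])
        records = [
            EnrichmentRecord(
                r.term_id, r.term_name, r.a, r.b, r.c, r.d, r.genes, r.fisher_p, r.chisq_p, float(q)
            )
            for r, q in zip(records, fdrs)
        ]
    return records


def select_network_genes(
    go_records: Sequence[EnrichmentRecord],
    pathway_records: Sequence[EnrichmentRecord],
    degs: DEGTable,
    matrix: ExpressionMatrix | None = None,
    p_max: float = DEFAULT_P_MAX,
    n_lnc: int = DEFAULT_N_LNC,
) -> list[str]:
    """Choose the genes that enter the co-expression networks.

    A DEG qualifies if it belongs to at least one significant GO term AND at
    least one significant pathway (raw Fisher p < ``p_max``, strict).  On
    top the ``n_lnc`` lncRNA-biotype genes with largest |log2fc| are added
    (ties broken lexicographically by gene id).  Output is deduplicated and
    deterministically ordered (qualifying DEGs sorted, then lncRNAs by
    descending |log2fc|).
    """
    called = set(degs.called_ids())

    def significant_members(records: Sequence[EnrichmentRecord]) -> set[str]:
        out: set[str] = set()
        for r in records:
            if r.fisher_p < p_max:
                out.update(r.genes)
        return out

    go_hits = significant_members(go_records) & called
    pw_hits = significant_members(pathway_records) & called
    selected = sorted(go_hits & pw_hits)

    lnc_selected: list[str] = []
    if n_lnc > 0:
        if matrix is None or matrix.gene_biotype is None:
            raise ValueError(
                "n_lnc > 0 requires a biotype-annotated matrix; set n_lnc=0 to skip lncRNA selection"
            )
        lfc = degs.log2fc_of()
        lnc = [
            g
            for g in matrix.gene_ids
            if matrix.gene_biotype.get(g) == "lncRNA" and g in lfc
        ]
        lnc.sort(key=lambda g: (-abs(lfc[g]), g))
        lnc_selected = lnc[:n_lnc]

    seen = set(selected)
    out = list(selected)
    for g in lnc_selected:
        if g not in seen:
            out.append(g)
            seen.add(g)
    return out


def enrichment_frame(records: Sequence[EnrichmentRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "term_id": [r.term_id for r in records],
            "term_name": [r.term_name for r in records],
            "a": [r.a for r in records],
            "b": [r.b for r in records],
            "c": [r.c for r in records],
            "d": [r.d for r in records],
            "fisher_p": [r.fisher_p for r in records],
            "chisq_p": [r.chisq_p for r in records],
            "fdr": [r.fdr for r in records],
        }
    )
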