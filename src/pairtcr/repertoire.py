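"""Chain pairing, efficiency tables, V-usage distributions and phenotype joins.

Efficiencies follow the "% of input cells" convention: the denominator is
the number of sorted cells per population (the sort manifest), not the
number of demultiplexed reads, so chain dropout anywhere between RT and
annotation lowers the percentage.  ``pct_paired <= min(pct_alpha,
pct_beta)`` holds by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd

from .amplicon import WellAddress
from .annotate import ChainRecord
from .reference import ReferenceSet


@dataclass
class PairedTCR:
    """One sorted well: its alpha and/or beta consensus records plus the
    index-sort phenotype row, where available."""

    well: WellAddress
    alpha: Optional[ChainRecord] = None
    beta: Optional[ChainRecord] = None
    population_label: Optional[str] = None
    phenotype: Optional[dict] = None
    phenotype_matched: bool = False

    @property
    def paired(self) -> bool:
        return self.alpha is not None and self.beta is not None


def _well_key(plate, row, column) -> WellAddress:
    return WellAddress(int(plate), str(row), int(column))


def pair_wells(alpha_records: Iterable[ChainRecord], beta_records: Iterable[ChainRecord],
               manifest: pd.DataFrame) -> tuple[list[PairedTCR], list[ChainRecord]]:
    """Attach chain records to the sorted wells listed in the manifest.

    ``manifest`` needs columns plate/row/column and (optionally)
    population_label.  Records for wells absent from the manifest are
    returned as orphans with a warning.
    """
    by_well: dict[WellAddress, dict[str, ChainRecord]] = {}
    for rec in list(alpha_records) + list(beta_records):
        slot = by_well.setdefault(rec.well, {})
        if rec.chain in slot:
            raise ValueError(f"duplicate {rec.chain} record for well {rec.well}")
        slot[rec.chain] = rec

    pairs, seen = [], set()
    for row in manifest.itertuples(index=False):
        well = _well_key(row.plate, row.row, row.column)
        if well in seen:
            raise ValueError(f"manifest lists well {well} twice")
        seen.add(well)
        recs = by_well.get(well, {})
        pairs.append(PairedTCR(
            well=well,
            alpha=recs.get("alpha"),
            beta=recs.get("beta"),
            population_label=getattr(row, "population_label", None),
        ))
    orphans = [r for w, recs in by_well.items() if w not in seen for r in recs.values()]
    if orphans:
        warnings.warn(f"{len(orphans)} chain record(s) in wells absent from the manifest")
    return pairs, orphans


def efficiency_table(pairs: Sequence[PairedTCR]) -> pd.DataFrame:
    """Per-population amplification/annotation efficiency (percent of sorted
    input cells yielding an alpha chain, a beta chain, or both)."""
    rows = []
    by_pop: dict[str, list[PairedTCR]] = {}
    for p in pairs:
        by_pop.setdefault(p.population_label or "all", []).append(p)
    for pop in sorted(by_pop):
        group = by_pop[pop]
        n = len(group)
        if n == 0:  # pragma: no cover - grouping never yields empty groups
            warnings.warn(f"population {pop!r} has 0 sorted cells; excluded")
            continue
        n_a = sum(p.alpha is not None for p in group)
        n_b = sum(p.beta is not None for p in group)
        n_ab = sum(p.paired for p in group)
        rows.append({
            "population": pop, "n_cells": n,
            "pct_alpha": round(100.0 * n_a / n, 1),
            "pct_beta": round(100.0 * n_b / n, 1),
            "pct_paired": round(100.0 * n_ab / n, 1),
        })
    return pd.DataFrame(rows, columns=["population", "n_cells", "pct_alpha",
                                       "pct_beta", "pct_paired"])


def v_usage(pairs: Sequence[PairedTCR], ref: Optional[ReferenceSet] = None,
            by_family: bool = False, group_by_population: bool = True) -> pd.DataFrame:
    """V-gene (or V-family) usage counts and relative frequencies.

    Frequencies are normalised within each (population, chain) group and
    sum to 1 per group.
    """
    rows = []
    for p in pairs:
        for rec in (p.alpha, p.beta):
            if rec is None:
                continue
            v = rec.v_hit.segment_id
            if by_family:
                if ref is None:
                    raise ValueError("by_family requires the reference set")
                v = ref[v].family
            rows.append({
                "population": (p.population_label or "all") if group_by_population else "all",
                "chain": rec.chain,
                "v": v,
            })
    if not rows:
        raise ValueError("v_usage needs at least one annotated record")
    df = pd.DataFrame(rows)
    counts = df.groupby(["population", "chain", "v"]).size().rename("count").reset_index()
    totals = counts.groupby(["population", "chain"])["count"].transform("sum")
    counts["frequency"] = counts["count"] / totals
    return counts


def link_phenotype(pairs: Sequence[PairedTCR], index_sort: pd.DataFrame) -> list[PairedTCR]:
    """Left-join index-sort phenotype rows onto the paired table (in place).

    Wells without an index row are flagged ``phenotype_matched=False``;
    duplicate index rows for one well raise.
    """
    key_cols = ["plate", "row", "column"]
    if index_sort.duplicated(subset=key_cols).any():
        dup = index_sort[index_sort.duplicated(subset=key_cols, keep=False)]
        raise ValueError(f"duplicate index-sort rows for wells:\n{dup[key_cols]}")
    lookup = {
        _well_key(r["plate"], r["row"], r["column"]): {
            k: v for k, v in r.items() if k not in key_cols
        }
        for r in index_sort.to_dict("records")
    }
    for p in pairs:
        row = lookup.get(p.well)
        p.phenotype = row
        p.phenotype_matched = row is not None
        if row is not None and p.population_label is None:
            p.population_label = row.get("population_label")
    return list(pairs)


def pairs_to_table(pairs: Sequence[PairedTCR]) -> pd.DataFrame:
    """Flat paired table (one row per sorted well)."""
    rows = []
    for p in pairs:
        row = {
            "plate": p.well.plate, "row": p.well.row, "column": p.well.column,
            "population": p.population_label,
            "paired": p.paired,
        }
        for chain, rec in (("alpha", p.alpha), ("beta", p.beta)):
            prefix = "a_" if chain == "alpha" else "b_"
            row[prefix + "v"] = rec.v_hit.segment_id if rec else "."
            row[prefix + "j"] = rec.j_hit.segment_id if rec else "."
            row[prefix + "cdr3_nt"] = rec.cdr3_nt if rec else "."
            row[prefix + "cdr3_aa"] = (rec.cdr3_aa or ".") if rec else "."
            row[prefix + "productive"] = rec.productive if rec else False
        rows.append(row)
    return pd.DataFrame(rows)


def plot_v_usage(usage: pd.DataFrame, ax=None):
    """Bar chart of V usage frequencies, one group of bars per population."""
    import matplotlib

    if ax is None:
        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        _, ax = plt.subplots(figsize=(10, 4))
    pivot = usage.pivot_table(index="v", columns="population", values="frequency",
                              fill_value=0.0)
    pivot.plot.bar(ax=ax)
    ax.set_ylabel("relative frequency")
    ax.set_xlabel("V gene")
    return ax
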