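"""Generic hypergeometric over-representation over named id sets (GMT)."""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from scipy import stats

from .diffexp import bh_adjust


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Named id sets from a GMT file (name, description, members...)."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = {m for m in parts[2:] if m}
    return sets


def overrepresentation(
    query: set[str], universe: set[str], sets: dict[str, set[str]]
) -> pd.DataFrame:
    """Upper hypergeometric tail P(X >= found) per set, BH-adjusted across sets.

    Population = |universe|, successes = |set & universe|, draws = |query|.
    The query must be a subset of the universe; sets are intersected with it.
    """
    if not universe:
        raise ValueError("empty universe")
    if not query <= universe:
        raise ValueError("query not a subset of universe")
    rows = []
    for name in sorted(sets):
        members = sets[name] & universe
        overlap = sorted(members & query)
        found = len(overlap)
        if members:
            p = float(stats.hypergeom(len(universe), len(members), len(query)).sf(found - 1))
        else:
            p = 1.0
        rows.append(
            {"set_name": name, "entities_found": found, "entities_total": len(members),
             "p_value": min(1.0, p), "overlap": ";".join(overlap)}
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["fdr"] = bh_adjust(out["p_value"].values)
    return out
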