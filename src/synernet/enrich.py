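"""Over-representation analysis shared by the metabolome and network stages.

One-sided Fisher exact enrichment (hypergeometric upper tail) of a hit set
against pathway memberships, with Benjamini-Hochberg adjustment across the
tested pathways.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import scipy.stats as sps
from statsmodels.stats.multitest import multipletests

from .datatypes import PathwayLibrary, ValidationError


def hypergeom_upper(k: int, M: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeom(population M, successes n, draws N)."""
    return float(sps.hypergeom.sf(k - 1, M, n, N))


def overrepresentation(
    hits: set[str],
    library: PathwayLibrary | dict[str, set[str]],
    universe: set[str],
) -> pd.DataFrame:
    """Hypergeometric over-representation p per pathway, BH-adjusted q.

    Pathway members outside the universe are ignored; a pathway with no
    members in the universe is excluded with a warning. Hits must lie in
    the universe. Rows sorted by ascending p (stable).

    Returns a DataFrame with columns
    ``pathway, hits, size, p, q`` (size = members within the universe).
    """
    if not universe:
        raise ValidationError("empty universe")
    stray = hits - universe
    if stray:
        raise ValidationError(f"hits outside the universe: {sorted(stray)[:5]}")
    members = library.members if isinstance(library, PathwayLibrary) else library
    rows = []
    M, N = len(universe), len(hits)
    for name in members:
        in_universe = members[name] & universe
        if not in_universe:
            warnings.warn(f"pathway {name!r} has no members in the universe; excluded")
            continue
        k = len(hits & in_universe)
        p = hypergeom_upper(k, M, len(in_universe), N) if N else 1.0
        rows.append((name, k, len(in_universe), p))
    df = pd.DataFrame(rows, columns=["pathway", "hits", "size", "p"])
    if df.empty:
        df["q"] = []
        return df
    df["q"] = bh_adjust(df["p"].to_numpy())
    return df.sort_values("p", kind="mergesort").reset_index(drop=True)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (q-values)."""
    return multipletests(np.asarray(p, dtype=float), method="fdr_bh")[1]
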