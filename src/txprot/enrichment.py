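"""Over-representation testing of gene lists against gene-set collections.

One-sided hypergeometric upper-tail tests of a query list against each
set (restricted to a stated universe), Benjamini-Hochberg adjusted
across sets.
"""

from __future__ import annotations

import warnings

import pandas as pd
from scipy import stats

from .core import ValidationError
from .diffexpr import bh_adjust

__all__ = [
    "read_gmt",
    "write_gmt",
    "hypergeom_tail",
    "select_regulated",
    "enrich",
]


def read_gmt(stream) -> dict[str, list[str]]:
    """Parse a GMT stream: name <TAB> description <TAB> member...

    Duplicate members within a set are removed with a warning; a line
    with fewer than three fields is an error carrying its line number.
    """
    sets: dict[str, list[str]] = {}
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValidationError(
                f"GMT line {lineno}: expected >= 3 tab-separated fields"
            )
        name, members = fields[0], fields[2:]
        deduped = list(dict.fromkeys(members))
        if len(deduped) < len(members):
            warnings.warn(f"GMT set {name!r}: duplicate members removed")
        sets[name] = deduped
    return sets


def write_gmt(sets: dict[str, list[str]], stream, description: str = "na"
              ) -> None:
    for name, members in sets.items():
        stream.write("\t".join([name, description, *members]) + "\n")


def hypergeom_tail(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, K, n).

    k = overlap, K = set size within universe, n = query size,
    N = universe size.
    """
    if not (0 <= k <= min(K, n) and 0 <= K <= N and 0 <= n <= N):
        raise ValidationError(
            f"inconsistent counts k={k}, K={K}, n={n}, N={N}"
        )
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def select_regulated(
    diff: pd.DataFrame, lfc_threshold: float = 1.0, direction: str = "up"
) -> list[str]:
    """Feature ids with log2fc >= threshold (up) or <= -threshold (down)."""
    if direction not in ("up", "down"):
        raise ValidationError(f"direction must be 'up' or 'down', got "
                              f"{direction!r}")
    if lfc_threshold < 0:
        raise ValidationError("lfc_threshold must be >= 0")
    lfc = diff["log2fc"]
    if direction == "up":
        keep = lfc >= lfc_threshold
    else:
        keep = lfc <= -lfc_threshold
    return list(diff.index[keep])


def enrich(
    query,
    universe,
    sets: dict[str, list[str]],
    fdr_threshold: float = 0.25,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` in each set.

    Sets are intersected with ``universe`` first; sets disjoint from it
    are skipped with a warning.  Returns one row per tested set with
    columns k, K, n, N, p, fdr, significant.
    """
    universe = list(dict.fromkeys(universe))
    uni = set(universe)
    query = list(dict.fromkeys(query))
    offenders = [q for q in query if q not in uni]
    if offenders:
        raise ValidationError(
            f"query ids outside the universe: {offenders[:10]}"
        )
    q = set(query)
    rows = []
    for name, members in sets.items():
        in_uni = uni & set(members)
        if not in_uni:
            warnings.warn(f"set {name!r} disjoint from the universe; skipped")
            continue
        k = len(q & in_uni)
        rows.append(
            {
                "set": name,
                "k": k,
                "K": len(in_uni),
                "n": len(q),
                "N": len(uni),
                "p": hypergeom_tail(k, len(in_uni), len(q), len(uni)),
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=["k", "K", "n", "N", "p", "fdr", "significant"]
        )
    table = pd.DataFrame(rows).set_index("set")
    table["fdr"] = bh_adjust(table["p"].to_numpy())
    table["significant"] = table["fdr"] < fdr_threshold
    return table
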