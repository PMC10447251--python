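"""Tentative metabolite identification and pathway frequency ranking.

Discriminating ion m/z values are matched against a local compound table
under an inclusive ppm tolerance, per adduct rule; pathway names are curated
by collapsing lipid side-chain detail to sum compositions, and pathways are
ranked by the number of unique discriminating m/z that hit one of their
member compounds. Ambiguous assignments are reported, never auto-resolved.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import ToyCompoundDB

__all__ = [
    "AnnotationMatch",
    "ADDUCTS",
    "adduct_mz",
    "match_ions",
    "shorten_lipid_name",
    "rank_pathways",
    "LipidNameError",
]

PROTON_MASS = 1.007276466812
CHLORIDE_MASS = 34.968852682

# adduct name -> neutral mass to observed m/z (singly charged)
ADDUCTS: dict[str, float] = {
    "[M-H]-": -PROTON_MASS,
    "[M+Cl]-": CHLORIDE_MASS,
    "[M+H]+": PROTON_MASS,
}

DEFAULT_NEGATIVE_ADDUCTS = ("[M-H]-", "[M+Cl]-")


class LipidNameError(ValueError):
    """Raised for a malformed lipid chain token."""


@dataclass
class AnnotationMatch:
    query_mz: float
    adduct: str
    compound_name: str
    theoretical_mz: float
    ppm_error: float            # signed: (observed - theoretical)/theoretical * 1e6
    pathways: list[tuple[str, str]]


def adduct_mz(neutral_mass: float, adduct: str) -> float:
    """Theoretical m/z of a neutral mass under an adduct rule."""
    if adduct not in ADDUCTS:
        raise ValueError(f"unknown adduct {adduct!r}; known: {sorted(ADDUCTS)}")
    return neutral_mass + ADDUCTS[adduct]


def match_ions(queries: np.ndarray | list[float], db: ToyCompoundDB,
               adducts: tuple[str, ...] = DEFAULT_NEGATIVE_ADDUCTS,
               ppm_tol: float = 5.0) -> list[AnnotationMatch]:
    """All (query, compound, adduct) matches within an inclusive ppm tolerance.

    A query may match several compounds (and one compound under several
    adducts); all are returned.
    """
    if not adducts:
        raise ValueError("adduct list must be non-empty")
    if ppm_tol <= 0:
        raise ValueError("ppm_tol must be positive")
    queries = np.asarray(queries, dtype=float)
    matches: list[AnnotationMatch] = []
    for adduct in adducts:
        theo = np.array([adduct_mz(r.monoisotopic_mass, adduct)
                         for r in db.records])
        order = np.argsort(theo, kind="stable")
        theo_sorted = theo[order]
        for q in queries:
            half = ppm_tol * 1e-6
            # |q - t| <= half * t  <=>  t in [q/(1+half), q/(1-half)]
            lo = np.searchsorted(theo_sorted, q / (1.0 + half), side="left")
            hi = np.searchsorted(theo_sorted, q / (1.0 - half), side="right")
            for idx in order[lo:hi]:
                t = theo[idx]
                ppm = (q - t) / t * 1e6
                if abs(ppm) <= ppm_tol + 1e-12:
                    rec = db.records[idx]
                    matches.append(AnnotationMatch(
                        query_mz=float(q), adduct=adduct,
                        compound_name=rec.compound_name, theoretical_mz=float(t),
                        ppm_error=float(ppm), pathways=list(rec.pathways)))
    return matches


# lipid token: CLASS(chain[/chain...]) with chain = C:D optionally followed
# by a parenthesised double-bond position annotation, e.g. 22:1(13Z)
_TOKEN_RE = re.compile(r"\b([A-Za-z][A-Za-z0-9]{0,7})\(([^()]*(?:\([^()]*\)[^()]*)*)\)")
_CHAIN_RE = re.compile(r"^(\d+):(\d+)(?:\(([^()]*)\))?$")


def _shorten_token(cls: str, body: str, original: str) -> str | None:
    """Collapse a chain body to a sum composition, or None if not lipid-like."""
    chains = [c.strip() for c in body.split("/")]
    if not any(re.search(r"\d+:", c) for c in chains):
        return None  # not a lipid token (e.g. a plain parenthetical)
    parsed = []
    for chain in chains:
        m = _CHAIN_RE.match(chain)
        if m is None:
            raise LipidNameError(
                f"malformed lipid chain token: {chain!r} in {original!r}")
        parsed.append((int(m.group(1)), int(m.group(2))))
    total_c = sum(c for c, _ in parsed)
    total_d = sum(d for _, d in parsed)
    return f"{cls}({total_c}:{total_d})"


def shorten_lipid_name(name: str) -> str:
    """Collapse lipid side-chain detail to the sum composition.

    ``PC(22:1(13Z)/20:0)`` becomes ``PC(42:1)``: carbons and double bonds
    are summed over side chains and double-bond position annotations are
    dropped. Already-shortened names and non-lipid text pass through
    unchanged; the transform is idempotent. Malformed chain tokens raise
    :class:`LipidNameError`.
    """
    def repl(m: re.Match) -> str:
        short = _shorten_token(m.group(1), m.group(2), m.group(0))
        return m.group(0) if short is None else short

    return _TOKEN_RE.sub(repl, name)


def rank_pathways(matches: list[AnnotationMatch]) -> pd.DataFrame:
    """Pathway ranking by number of unique discriminating m/z.

    Pathway names are first curated (lipid tokens shortened); pathways in
    the same subclass that collapse to the same curated name are merged.
    A query m/z counts once per pathway regardless of how many member
    compounds it matched. Sorted by count descending, ties alphabetical.
    Returns columns (pathway, subclass, n_unique_mz, member_mz).
    """
    members: dict[tuple[str, str], set[float]] = {}
    for m in matches:
        for pathway, subclass in m.pathways:
            key = (shorten_lipid_name(pathway), subclass)
            members.setdefault(key, set()).add(m.query_mz)
    rows = [
        {"pathway": name, "subclass": sub, "n_unique_mz": len(mzs),
         "member_mz": sorted(mzs)}
        for (name, sub), mzs in members.items()
    ]
    df = pd.DataFrame(rows, columns=["pathway", "subclass", "n_unique_mz",
                                     "member_mz"])
    if len(df):
        df = (df.sort_values(["n_unique_mz", "pathway"],
                             ascending=[False, True], kind="stable")
              .reset_index(drop=True))
    return df
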