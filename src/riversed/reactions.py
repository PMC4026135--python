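"""Reaction catalogues and the environmental transformation matrix (ETM).

The ETM is a weighted metabolites x enzymes matrix derived from reaction
stoichiometry.  Sign convention: a metabolite consumed by an enzyme's
reactions (a substrate) receives a positive weight, a produced metabolite
(a product) a negative weight, so that projecting an *increase* in that
enzyme's gene abundance through the matrix yields a positive score for
metabolites the community can consume more of, and a negative score for
metabolites that would relatively accumulate.

Flat-file formats
-----------------
Reaction catalogue: TSV with 5 columns --
``reaction_id  ec  substrates  products  reversible`` where substrates and
products are comma-separated ``metabolite:coefficient`` tokens and reversible
is 0/1.  Lines starting with ``#`` are comments.

Pathway map: two-column TSV ``metabolite_id  pathway_id``, one pair per line;
a metabolite may appear on several lines (multi-membership).
"""

from __future__ import annotations

import re
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from ._utils import ReactionParseError, RiversedError

_EC_RE = re.compile(r"^\d+\.(\d+|-)\.(\d+|-)\.(\d+|-)$")


def _net_sides(
    substrates: tuple[tuple[str, float], ...], products: tuple[tuple[str, float], ...]
) -> tuple[tuple[tuple[str, float], ...], tuple[tuple[str, float], ...]]:
    """Apply the net-coefficient rule for metabolites on both sides."""
    sub = defaultdict(float)
    for m, c in substrates:
        sub[m] += float(c)
    prod = defaultdict(float)
    for m, c in products:
        prod[m] += float(c)
    for m in set(sub) & set(prod):
        net = sub[m] - prod[m]
        del sub[m], prod[m]
        if net > 0:
            sub[m] = net
        elif net < 0:
            prod[m] = -net
        # net == 0: dropped from both sides
    return tuple(sorted(sub.items())), tuple(sorted(prod.items()))


@dataclass(frozen=True)
class Reaction:
    """One enzyme-catalysed reaction with integer-or-real stoichiometry."""

    reaction_id: str
    ec: str
    substrates: tuple[tuple[str, float], ...]
    products: tuple[tuple[str, float], ...]
    reversible: bool = False

    def __post_init__(self):
        subs, prods = _net_sides(tuple(self.substrates), tuple(self.products))
        if not subs or not prods:
            raise RiversedError(
                f"reaction {self.reaction_id}: substrates and products must be "
                "non-empty after net-coefficient reduction"
            )
        if any(c <= 0 for _, c in subs + prods):
            raise RiversedError(
                f"reaction {self.reaction_id}: stoichiometric coefficients must be > 0"
            )
        if not _EC_RE.match(self.ec):
            raise RiversedError(f"reaction {self.reaction_id}: malformed EC '{self.ec}'")
        object.__setattr__(self, "substrates", subs)
        object.__setattr__(self, "products", prods)

    def reversed_(self) -> "Reaction":
        """The same reaction written in the opposite direction."""
        return Reaction(self.reaction_id, self.ec, self.products, self.substrates, self.reversible)

    @property
    def metabolites(self) -> set[str]:
        return {m for m, _ in self.substrates} | {m for m, _ in self.products}


@dataclass(frozen=True)
class ReactionSet:
    """An ordered collection of reactions, grouped by catalysing enzyme (EC)."""

    reactions: tuple[Reaction, ...]

    def __post_init__(self):
        object.__setattr__(self, "reactions", tuple(self.reactions))
        seen = set()
        for r in self.reactions:
            if r.reaction_id in seen:
                raise RiversedError(f"duplicate reaction_id '{r.reaction_id}'")
            seen.add(r.reaction_id)

    def __len__(self) -> int:
        return len(self.reactions)

    def __iter__(self):
        return iter(self.reactions)

    def by_enzyme(self) -> dict[str, list[Reaction]]:
        out: dict[str, list[Reaction]] = defaultdict(list)
        for r in self.reactions:
            out[r.ec].append(r)
        return dict(out)

    @property
    def enzymes(self) -> list[str]:
        return sorted({r.ec for r in self.reactions})

    @property
    def metabolites(self) -> list[str]:
        return sorted(set().union(*(r.metabolites for r in self.reactions)))


@dataclass(frozen=True)
class ETM:
    """Environmental transformation matrix: metabolites (rows) x enzymes (cols).

    ``matrix`` is a dense DataFrame; enzymes with no reactions never appear
    as columns (guaranteed by construction from a ReactionSet).
    """

    matrix: pd.DataFrame
    normalization: str = "per_enzyme"

    @property
    def metabolites(self) -> list[str]:
        return list(self.matrix.index)

    @property
    def enzymes(self) -> list[str]:
        return list(self.matrix.columns)


def build_etm(reactions: ReactionSet, normalization: str = "per_enzyme") -> ETM:
    """Accumulate reaction stoichiometry into the ETM.

    Each irreversible reaction of enzyme ``e`` contributes ``+coef`` for each
    substrate and ``-coef`` for each product to column ``e``.  Reversible
    reactions contribute in their written direction only.  With
    ``normalization='per_enzyme'`` (default) each column is divided by the
    number of reactions that enzyme catalyses, so promiscuous enzymes do not
    dominate; ``'none'`` leaves raw sums.
    """
    if normalization not in ("per_enzyme", "none"):
        raise ValueError(f"unknown normalization '{normalization}'")
    if len(reactions) == 0:
        raise RiversedError("cannot build an ETM from an empty reaction set")
    cols: dict[str, dict[str, float]] = {}
    for ec, rxns in reactions.by_enzyme().items():
        acc: dict[str, float] = defaultdict(float)
        for r in rxns:
            for m, c in r.substrates:
                acc[m] += c
            for m, c in r.products:
                acc[m] -= c
        if normalization == "per_enzyme":
            acc = {m: v / len(rxns) for m, v in acc.items()}
        cols[ec] = dict(acc)
    mat = pd.DataFrame(cols).fillna(0.0)
    mat = mat.reindex(index=sorted(mat.index), columns=sorted(mat.columns))
    return ETM(matrix=mat, normalization=normalization)


class PathwayMap:
    """Mapping metabolite id -> set of pathway ids (multi-membership)."""

    def __init__(self, mapping: dict[str, set[str]] | None = None):
        self._map: dict[str, frozenset[str]] = {
            m: frozenset(ps) for m, ps in (mapping or {}).items()
        }
        for m, ps in self._map.items():
            if any(not p for p in ps):
                raise RiversedError(f"metabolite {m}: empty pathway id")

    def __len__(self) -> int:
        return len(self._map)

    def __eq__(self, other) -> bool:
        return isinstance(other, PathwayMap) and self._map == other._map

    def lookup(self, metabolite: str) -> frozenset[str]:
        """Pathways containing a metabolite; empty set if unknown."""
        return self._map.get(metabolite, frozenset())

    @property
    def metabolites(self) -> list[str]:
        return sorted(self._map)

    @property
    def pathways(self) -> list[str]:
        out: set[str] = set()
        for ps in self._map.values():
            out |= ps
        return sorted(out)

    def members(self, pathway: str) -> list[str]:
        return sorted(m for m, ps in self._map.items() if pathway in ps)


def _parse_side(token: str, path: str, lineno: int) -> tuple[tuple[str, float], ...]:
    out = []
    for part in token.split(","):
        part = part.strip()
        if not part:
            continue
        if ":" not in part:
            raise ReactionParseError(f"{path}:{lineno}: bad stoichiometry token '{part}'")
        mid, _, coef = part.rpartition(":")
        try:
            coef_f = float(coef)
        except ValueError:
            raise ReactionParseError(
                f"{path}:{lineno}: non-numeric coefficient '{coef}' for '{mid}'"
            ) from None
        if not mid.strip():
            raise ReactionParseError(f"{path}:{lineno}: empty metabolite id in '{part}'")
        out.append((mid.strip(), coef_f))
    return tuple(out)


def parse_reactions(path: str | Path) -> ReactionSet:
    """Parse a 5-column reaction catalogue TSV into a ReactionSet."""
    path = Path(path)
    reactions: list[Reaction] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = [f.strip() for f in line.split("\t")]
            if len(fields) != 5:
                raise ReactionParseError(
                    f"{path}:{lineno}: expected 5 tab-separated fields, got {len(fields)}"
                )
            rid, ec, subs_s, prods_s, rev_s = fields
            if rid in seen:
                raise ReactionParseError(f"{path}:{lineno}: duplicate reaction_id '{rid}'")
            seen.add(rid)
            if rev_s not in ("0", "1"):
                raise ReactionParseError(
                    f"{path}:{lineno}: reversible flag must be 0 or 1, got '{rev_s}'"
                )
            subs = _parse_side(subs_s, str(path), lineno)
            prods = _parse_side(prods_s, str(path), lineno)
            try:
                reactions.append(Reaction(rid, ec, subs, prods, rev_s == "1"))
            except RiversedError as e:
                raise ReactionParseError(f"{path}:{lineno}: {e}") from None
    return ReactionSet(tuple(reactions))


def write_reactions(reactions: ReactionSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# reaction_id\tec\tsubstrates\tproducts\treversible\n")
        for r in reactions:
            subs = ",".join(f"{m}:{c:g}" for m, c in r.substrates)
            prods = ",".join(f"{m}:{c:g}" for m, c in r.products)
            fh.write(f"{r.reaction_id}\t{r.ec}\t{subs}\t{prods}\t{int(r.reversible)}\n")


def parse_pathway_map(path: str | Path) -> PathwayMap:
    """Parse a two-column metabolite/pathway TSV into a PathwayMap."""
    path = Path(path)
    mapping: dict[str, set[str]] = defaultdict(set)
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = [f.strip() for f in line.split("\t")]
            if len(fields) != 2:
                raise ReactionParseError(
                    f"{path}:{lineno}: expected 2 tab-separated fields, got {len(fields)}"
                )
            met, pw = fields
            if not pw:
                raise ReactionParseError(f"{path}:{lineno}: empty pathway id")
            if not met:
                raise ReactionParseError(f"{path}:{lineno}: empty metabolite id")
            mapping[met].add(pw)
    return PathwayMap(dict(mapping))


def write_pathway_map(pmap: PathwayMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# metabolite_id\tpathway_id\n")
        for m in pmap.metabolites:
            for p in sorted(pmap.lookup(m)):
                fh.write(f"{m}\t{p}\n")
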