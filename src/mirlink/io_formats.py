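"""Readers and writers for the external file dialects the tool consumes.

Five plain-text dialects are supported:

* two-column deregulation lists (identifier, direction ``1``/``-1``),
  one for miRNAs (miRBase-style ids such as ``hsa-miR-23b``) and one for
  genes (HGNC symbols);
* a tab-delimited miRNA -> target-gene interaction table with an optional
  prediction p-value column (microCosm-style), filtered at an alpha level;
* gene-set categories in GMT format;
* miRNA families in the miRBase ``miFam.dat`` dialect;
* network exports in GraphML and SIF.

All readers validate strictly and normalise identifiers: gene symbols are
upper-cased, miRNA ids keep their case but are compared case-insensitively,
and both the ASCII hyphen and the Unicode minus sign are accepted as the
down-regulation marker.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import networkx as nx

MIRNA = "miRNA"
GENE = "gene"

#: direction tokens accepted in deregulation files (Unicode minus included)
_UP_TOKENS = {"1", "+1"}
_DOWN_TOKENS = {"-1", "−1", "–1"}


class ParseError(ValueError):
    """A file violated its dialect; the message names the offending line."""


def normalize_identifier(identifier: str, entity_class: str) -> str:
    """Return the comparison key for an identifier of the given class."""
    identifier = identifier.strip()
    if entity_class == GENE:
        return identifier.upper()
    return identifier.lower()


# ---------------------------------------------------------------------------
# deregulation lists
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DeregulationSet:
    """Identifiers of one entity class called up- (+1) or down- (-1) regulated.

    ``entries`` maps the display identifier (genes upper-cased, miRNA case
    preserved) to its direction.  Lookups through :meth:`direction_of` and
    :meth:`__contains__` are case-insensitive for miRNAs.
    """

    entity_class: str
    entries: Mapping[str, int]
    _index: Mapping[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.entity_class not in (MIRNA, GENE):
            raise ValueError(f"unknown entity class {self.entity_class!r}")
        index: dict[str, int] = {}
        for identifier, direction in self.entries.items():
            if direction not in (+1, -1):
                raise ValueError(
                    f"direction for {identifier!r} must be +1 or -1, got {direction!r}"
                )
            key = normalize_identifier(identifier, self.entity_class)
            if key in index and index[key] != direction:
                raise ValueError(f"conflicting directions for {identifier!r}")
            index[key] = direction
        object.__setattr__(self, "_index", index)

    def __len__(self) -> int:
        return len(self._index)

    def __contains__(self, identifier: str) -> bool:
        return normalize_identifier(identifier, self.entity_class) in self._index

    def direction_of(self, identifier: str) -> int | None:
        """Direction of ``identifier`` (+1/-1) or None if not deregulated."""
        return self._index.get(normalize_identifier(identifier, self.entity_class))

    def ids(self, direction: int | None = None) -> frozenset[str]:
        """Normalised identifiers, optionally restricted to one direction."""
        return frozenset(
            key for key, d in self._index.items() if direction is None or d == direction
        )

    @property
    def n_up(self) -> int:
        return sum(1 for d in self._index.values() if d == +1)

    @property
    def n_down(self) -> int:
        return sum(1 for d in self._index.values() if d == -1)

    @property
    def directions_present(self) -> frozenset[int]:
        return frozenset(self._index.values())


def _parse_direction(token: str, lineno: int, path: object) -> int:
    if token in _UP_TOKENS:
        return +1
    if token in _DOWN_TOKENS:
        return -1
    raise ParseError(f"{path}:{lineno}: malformed direction token {token!r} (expected 1 or -1)")


def read_deregulation_file(path: str | Path, entity_class: str) -> DeregulationSet:
    """Parse a two-column identifier/direction list.

    Duplicate identical lines are deduplicated silently; the same identifier
    with conflicting directions is an error.
    """
    path = Path(path)
    entries: dict[str, int] = {}
    seen_keys: dict[str, str] = {}
    with path.open() as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) != 2:
                raise ParseError(f"{path}:{lineno}: expected two columns, got {len(parts)}")
            identifier, token = parts[0].strip(), parts[1].strip()
            if not identifier:
                raise ParseError(f"{path}:{lineno}: empty identifier")
            direction = _parse_direction(token, lineno, path)
            display = identifier.upper() if entity_class == GENE else identifier
            key = normalize_identifier(identifier, entity_class)
            if key in seen_keys:
                if entries[seen_keys[key]] != direction:
                    raise ParseError(
                        f"{path}:{lineno}: identifier {identifier!r} listed with "
                        "conflicting directions"
                    )
                continue
            seen_keys[key] = display
            entries[display] = direction
    return DeregulationSet(entity_class=entity_class, entries=entries)


def write_deregulation_file(dereg: DeregulationSet, path: str | Path) -> None:
    """Serialise a deregulation set (sorted by identifier) as two-column TSV."""
    path = Path(path)
    with path.open("w") as handle:
        for identifier in sorted(dereg.entries):
            handle.write(f"{identifier}\t{dereg.entries[identifier]}\n")


# ---------------------------------------------------------------------------
# interaction table
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class InteractionTable:
    """Unique (miRNA, gene) regulatory pairs with optional prediction scores.

    The regulatory universe of the analysis: every statistic downstream is
    computed over these pairs and the identifiers occurring in them.
    """

    pairs: tuple[tuple[str, str, float | None], ...]
    organism_prefix: str

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        for mirna, gene, score in self.pairs:
            key = (mirna.lower(), gene.upper())
            if key in seen:
                raise ValueError(f"duplicate interaction pair {key}")
            seen.add(key)
            if score is not None and not (0.0 <= score <= 1.0):
                raise ValueError(f"score {score} for pair {key} outside [0, 1]")

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def mirna_ids(self) -> frozenset[str]:
        """Normalised (lower-case) miRNA identifiers."""
        return frozenset(m.lower() for m, _, _ in self.pairs)

    @property
    def gene_ids(self) -> frozenset[str]:
        return frozenset(g.upper() for _, g, _ in self.pairs)

    def pair_keys(self) -> tuple[tuple[str, str], ...]:
        """Normalised (mirna, gene) keys, one per pair, in table order."""
        return tuple((m.lower(), g.upper()) for m, g, _ in self.pairs)

    def targets_of(self, mirna: str) -> frozenset[str]:
        key = mirna.lower()
        return frozenset(g.upper() for m, g, _ in self.pairs if m.lower() == key)


def _organism_prefix(mirna_id: str) -> str:
    return mirna_id.split("-", 1)[0].lower()


def read_interaction_table(path: str | Path, score_threshold: float = 0.01) -> InteractionTable:
    """Parse a miRNA/gene/score table, keeping rows with score < threshold.

    Rows without a score column are always retained.  Duplicate pairs collapse
    to the smallest score.  All miRNA ids must share one organism prefix (the
    token before the first ``-``), from which the organism is inferred.
    """
    path = Path(path)
    if not 0.0 < score_threshold <= 1.0:
        raise ValueError("score_threshold must lie in (0, 1]")
    best: dict[tuple[str, str], tuple[str, str, float | None]] = {}
    prefixes: set[str] = set()
    with path.open() as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) not in (2, 3):
                raise ParseError(f"{path}:{lineno}: expected 2 or 3 columns, got {len(parts)}")
            mirna, gene = parts[0].strip(), parts[1].strip().upper()
            score: float | None = None
            if len(parts) == 3:
                try:
                    score = float(parts[2])
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: malformed score {parts[2]!r}") from exc
                if not 0.0 <= score <= 1.0:
                    raise ParseError(f"{path}:{lineno}: score {score} outside [0, 1]")
                if score >= score_threshold:
                    continue
            prefixes.add(_organism_prefix(mirna))
            if len(prefixes) > 1:
                raise ParseError(
                    f"{path}:{lineno}: mixed organism prefixes {sorted(prefixes)}"
                )
            key = (mirna.lower(), gene)
            if key in best:
                old_score = best[key][2]
                if score is not None and (old_score is None or score < old_score):
                    best[key] = (mirna, gene, score)
            else:
                best[key] = (mirna, gene, score)
    if not best:
        raise ParseError(f"{path}: no interactions retained at threshold {score_threshold}")
    pairs = tuple(best[key] for key in sorted(best))
    return InteractionTable(pairs=pairs, organism_prefix=next(iter(prefixes)))


def write_interaction_table(table: InteractionTable, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as handle:
        for mirna, gene, score in sorted(table.pairs):
            if score is None:
                handle.write(f"{mirna}\t{gene}\n")
            else:
                # repr round-trips the float exactly; a rounded rendering could
                # push a score across the filter threshold on re-read
                handle.write(f"{mirna}\t{gene}\t{score!r}\n")


# ---------------------------------------------------------------------------
# GMT categories
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CategoryDB:
    """Named gene sets (biological categories) used by the enrichment tests."""

    categories: Mapping[str, frozenset[str]]
    source_label: str = ""

    def __post_init__(self) -> None:
        for name, members in self.categories.items():
            if not members:
                raise ValueError(f"category {name!r} has no members")

    def __len__(self) -> int:
        return len(self.categories)


def read_gmt(path: str | Path, source_label: str | None = None) -> CategoryDB:
    """Parse a GMT file: name, description, then member gene ids, tab-separated."""
    path = Path(path)
    categories: dict[str, frozenset[str]] = {}
    with path.open() as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(
                    f"{path}:{lineno}: GMT line needs name, description and >= 1 member"
                )
            name = parts[0].strip()
            members = frozenset(p.strip().upper() for p in parts[2:] if p.strip())
            if not members:
                raise ParseError(f"{path}:{lineno}: category {name!r} has no members")
            if name in categories:
                raise ParseError(f"{path}:{lineno}: duplicate category name {name!r}")
            categories[name] = members
    return CategoryDB(categories=categories, source_label=source_label or path.stem)


def write_gmt(db: CategoryDB, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as handle:
        for name in sorted(db.categories):
            members = "\t".join(sorted(db.categories[name]))
            handle.write(f"{name}\t{db.source_label}\t{members}\n")


# ---------------------------------------------------------------------------
# miFam families
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FamilyDB:
    """miRNA families (shared seed/origin); a miRNA belongs to at most one."""

    families: Mapping[str, frozenset[str]]

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for name, members in self.families.items():
            if not members:
                raise ValueError(f"family {name!r} has no members")
            for member in members:
                key = member.lower()
                if key in seen and seen[key] != name:
                    raise ValueError(
                        f"miRNA {member!r} in both {seen[key]!r} and {name!r}"
                    )
                seen[key] = name

    def __len__(self) -> int:
        return len(self.families)

    def members_normalized(self, name: str) -> frozenset[str]:
        return frozenset(m.lower() for m in self.families[name])


def read_mifam(path: str | Path) -> FamilyDB:
    """Parse the miFam dialect: ``AC``/``ID``/``MI`` lines, ``//`` separators.

    The last whitespace-separated token of each ``MI`` line is the miRNA id.
    """
    path = Path(path)
    families: dict[str, frozenset[str]] = {}
    name: str | None = None
    members: list[str] = []
    saw_record_content = False
    with path.open() as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if line.strip() == "//":
                if name is None:
                    if saw_record_content:
                        raise ParseError(f"{path}:{lineno}: record missing ID line")
                    continue
                if name in families:
                    raise ParseError(f"{path}:{lineno}: duplicate family {name!r}")
                families[name] = frozenset(members)
                name, members, saw_record_content = None, [], False
                continue
            if not line.strip():
                continue
            tag, _, rest = line.partition(" ")
            rest = rest.strip()
            saw_record_content = True
            if tag == "ID":
                name = rest
            elif tag == "MI":
                tokens = rest.split()
                if not tokens:
                    raise ParseError(f"{path}:{lineno}: empty MI line")
                members.append(tokens[-1])
            elif tag == "AC":
                pass
            else:
                raise ParseError(f"{path}:{lineno}: unknown tag {tag!r}")
    if saw_record_content:
        raise ParseError(f"{path}: final record not terminated by // or missing ID")
    return FamilyDB(families=families)


def write_mifam(db: FamilyDB, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as handle:
        for idx, name in enumerate(sorted(db.families), start=1):
            handle.write(f"AC   MIPF{idx:07d}\n")
            handle.write(f"ID   {name}\n")
            for member_idx, member in enumerate(sorted(db.families[name]), start=1):
                handle.write(f"MI   MI{member_idx:07d}  {member}\n")
            handle.write("//\n")


# ---------------------------------------------------------------------------
# network export
# ---------------------------------------------------------------------------


def write_graphml(graph: nx.Graph, path: str | Path) -> None:
    """Export with node attributes node_class, regulation and degree intact."""
    nx.write_graphml(graph, str(path), named_key_ids=True)


def write_sif(graph: nx.Graph, path: str | Path) -> None:
    """Write SIF lines ``<miRNA> targets <gene>``; disease edges use
    ``associated_with`` with the disease vertex as source."""
    path = Path(path)
    lines: list[str] = []
    for u, v in graph.edges():
        cu = graph.nodes[u].get("node_class")
        cv = graph.nodes[v].get("node_class")
        if {cu, cv} == {"miRNA", "gene"}:
            src, dst = (u, v) if cu == "miRNA" else (v, u)
            lines.append(f"{src}\ttargets\t{dst}")
        else:
            src, dst = (u, v) if cu == "disease" else (v, u)
            lines.append(f"{src}\tassociated_with\t{dst}")
    with path.open("w") as handle:
        for line in sorted(lines):
            handle.write(line + "\n")


def read_sif(path: str | Path) -> list[tuple[str, str, str]]:
    """Read back (source, relation, target) triples; used for round-trips."""
    triples: list[tuple[str, str, str]] = []
    with Path(path).open() as handle:
        for raw in handle:
            line = raw.strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ParseError(f"{path}: malformed SIF line {line!r}")
            triples.append((parts[0], parts[1], parts[2]))
    return triples
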