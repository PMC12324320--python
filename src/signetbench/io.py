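"""Network file I/O.

Two dialects are supported:

``netflux_tables``
    The two-table species/reactions layout used by Netflux-style model
    exchange. As an ``.xlsx`` workbook the tables live on sheets named
    ``species`` (columns ID, name, y0, ymax, tau) and ``reactions`` (columns
    rule, weight, n, EC50). As plain text the two tables are stacked in one
    file with ``# species`` / ``# reactions`` section markers, each section a
    CSV with the same header; ``# network:`` and ``# phenotype:`` header lines
    carry metadata.

``edge_list``
    Three-column delimited text ``source <tab> interaction <tab> target`` with
    interaction in {activates, inhibits} (SIF-like), for interchange. Node
    parameters and input reactions are not representable in this dialect.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import pandas as pd

from .network import (
    Network,
    NetworkValidationError,
    Node,
    Reaction,
    SignedEdge,
    network_from_edges,
)

__all__ = ["read_network", "write_network"]

_SPECIES_COLS = ["ID", "name", "y0", "ymax", "tau"]
_REACTION_COLS = ["rule", "weight", "n", "EC50"]


def _network_from_tables(species: pd.DataFrame, reactions: pd.DataFrame,
                         name: str, phenotype: str) -> Network:
    nodes = [
        Node(
            id=str(row["ID"]),
            label="" if pd.isna(row.get("name")) else str(row.get("name", "")),
            y0=float(row["y0"]),
            ymax=float(row["ymax"]),
            tau=float(row["tau"]),
        )
        for _, row in species.iterrows()
    ]
    rxns = [
        Reaction(
            rule=str(row["rule"]),
            weight=float(row["weight"]),
            n=float(row["n"]),
            ec50=float(row["EC50"]),
        )
        for _, row in reactions.iterrows()
    ]
    return Network(name=name, phenotype=phenotype, nodes=nodes, reactions=rxns)


def _tables_from_network(net: Network) -> tuple[pd.DataFrame, pd.DataFrame]:
    species = pd.DataFrame(
        [[n.id, n.label, n.y0, n.ymax, n.tau] for n in net.nodes], columns=_SPECIES_COLS
    )
    reactions = pd.DataFrame(
        [[r.rule, r.weight, r.n, r.ec50] for r in net.reactions], columns=_REACTION_COLS
    )
    return species, reactions


def _read_netflux_text(path: Path) -> Network:
    name = phenotype = ""
    sections: dict[str, list[str]] = {}
    current: list[str] | None = None
    for line in path.read_text().splitlines():
        stripped = line.strip()
        if stripped.startswith("# network:"):
            name = stripped.split(":", 1)[1].strip()
        elif stripped.startswith("# phenotype:"):
            phenotype = stripped.split(":", 1)[1].strip()
        elif stripped.lower() in ("# species", "# reactions"):
            current = sections.setdefault(stripped[2:].lower(), [])
        elif current is not None and stripped:
            current.append(line)
    if "species" not in sections or "reactions" not in sections:
        raise NetworkValidationError(f"{path}: missing '# species' or '# reactions' section")

    def _frame(lines: list[str], cols: list[str]) -> pd.DataFrame:
        if len(lines) <= 1:  # header only
            return pd.DataFrame(columns=cols)
        return pd.read_csv(_io.StringIO("\n".join(lines)))

    species = _frame(sections["species"], _SPECIES_COLS)
    reactions = _frame(sections["reactions"], _REACTION_COLS)
    return _network_from_tables(species, reactions, name, phenotype)


def _write_netflux_text(net: Network, path: Path) -> None:
    species, reactions = _tables_from_network(net)
    with path.open("w") as fh:
        fh.write(f"# network: {net.name}\n# phenotype: {net.phenotype}\n")
        fh.write("# species\n")
        species.to_csv(fh, index=False)
        fh.write("# reactions\n")
        reactions.to_csv(fh, index=False)


def read_network(path: str | Path, dialect: str = "netflux_tables") -> Network:
    """Read and validate a network file in the named dialect."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "netflux_tables":
        if path.suffix.lower() == ".xlsx":
            species = pd.read_excel(path, sheet_name="species")
            reactions = pd.read_excel(path, sheet_name="reactions")
            return _network_from_tables(species, reactions, path.stem, "")
        return _read_netflux_text(path)
    if dialect == "edge_list":
        frame = pd.read_csv(path, sep=None, engine="python",
                            names=["source", "interaction", "target"], comment="#")
        edges = set()
        for _, row in frame.iterrows():
            kind = str(row["interaction"]).strip().lower()
            if kind not in ("activates", "inhibits"):
                raise NetworkValidationError(f"unknown interaction type: {kind!r}")
            sign = +1 if kind == "activates" else -1
            edges.add(SignedEdge(str(row["source"]), str(row["target"]), sign))
        net = network_from_edges(edges, name=path.stem)
        # interchange dialect: drop the synthesized basal input reactions
        net.reactions = [r for r in net.reactions if not r.is_input]
        return net
    raise ValueError(f"unknown dialect: {dialect!r}")


def write_network(net: Network, path: str | Path, dialect: str = "netflux_tables") -> None:
    """Write a network; ``read_network(write_network(net))`` round-trips."""
    path = Path(path)
    if dialect == "netflux_tables":
        if path.suffix.lower() == ".xlsx":
            from openpyxl import Workbook

            species, reactions = _tables_from_network(net)
            book = Workbook()
            sheet = book.active
            sheet.title = "species"
            sheet.append(_SPECIES_COLS)
            for row in species.itertuples(index=False):
                sheet.append(list(row))
            rxn_sheet = book.create_sheet("reactions")
            rxn_sheet.append(_REACTION_COLS)
            for row in reactions.itertuples(index=False):
                rxn_sheet.append(list(row))
                # rules like "=> A" must stay text, not become Excel formulas
                rxn_sheet.cell(row=rxn_sheet.max_row, column=1).data_type = "s"
            book.save(path)
            return
        _write_netflux_text(net, path)
        return
    if dialect == "edge_list":
        from .network import to_signed_edges

        rows = [
            (e.source, "activates" if e.sign > 0 else "inhibits", e.target)
            for e in sorted(to_signed_edges(net))
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)
        return
    raise ValueError(f"unknown dialect: {dialect!r}")
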