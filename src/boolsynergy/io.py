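"""Delimited-text readers/writers for every pipeline table, plus manifests.

All artifacts are plain TSV (diff-able, language-neutral) with a JSON manifest
sidecar recording the seed and configuration that produced them.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .network import (
    MutationTable,
    NetworkValidationError,
    RuleOverrideTable,
    RuleSet,
    SignalingNetwork,
    normalize_sign,
)
from .logic import parse_expression
from .perturb import Drug

__all__ = [
    "read_network",
    "write_network",
    "read_rule_table",
    "write_rule_table",
    "read_mutation_table",
    "write_mutation_table",
    "read_override_table",
    "read_expression",
    "write_expression",
    "read_drug_table",
    "write_drug_table",
    "read_pair_table",
    "write_pair_table",
    "read_role_table",
    "write_role_table",
    "write_activity_long",
    "write_manifest",
    "write_scenario",
]

_SIF_RELATIONS = {"activates", "inhibits"}


class TableFormatError(ValueError):
    """Raised when a delimited input table cannot be parsed."""

    def __init__(self, path, line: int | None, message: str):
        self.path = str(path)
        self.line = line
        where = f"{path}" + (f", line {line}" if line is not None else "")
        super().__init__(f"{where}: {message}")


def read_network(path: str | Path) -> SignalingNetwork:
    """Read a signed edge list.

    Accepts either a headered TSV with columns ``source, target, sign``
    (sign in {+, -, activating, inhibitory}) or the SIF dialect
    ``source<TAB>relation<TAB>target`` with relation in {activates, inhibits}.
    """
    path = Path(path)
    lines = [
        ln for ln in path.read_text().splitlines() if ln.strip() and not ln.startswith("#")
    ]
    if not lines:
        raise TableFormatError(path, None, "empty edge-list file")
    first = lines[0].split("\t")
    edges: list[tuple[str, str, str]] = []
    is_sif = len(first) == 3 and first[1].strip().lower() in _SIF_RELATIONS
    start = 0 if is_sif else 1
    if not is_sif:
        header = [c.strip().lower() for c in first]
        if header[:3] != ["source", "target", "sign"]:
            raise TableFormatError(
                path, 1, f"expected header 'source\\ttarget\\tsign' or SIF rows, got {first}"
            )
    for i, line in enumerate(lines[start:], start=start + 1):
        fields = [f.strip() for f in line.split("\t")]
        if len(fields) < 3:
            raise TableFormatError(path, i, f"expected 3 columns, got {len(fields)}")
        if is_sif:
            src, relation, tgt = fields[:3]
            sign = relation
        else:
            src, tgt, sign = fields[:3]
        try:
            edges.append((src, tgt, normalize_sign(sign)))
        except NetworkValidationError as exc:
            raise TableFormatError(path, i, str(exc)) from exc
    nodes = sorted({n for s, t, _ in edges for n in (s, t)})
    return SignalingNetwork(nodes=nodes, edges=edges)


def write_network(network: SignalingNetwork, path: str | Path):
    rows = ["source\ttarget\tsign"]
    rows += [
        f"{s}\t{t}\t{'+' if sign == 'activating' else '-'}" for s, t, sign in network.edges
    ]
    Path(path).write_text("\n".join(rows) + "\n")


def read_rule_table(path: str | Path, clamps: Mapping[str, int] | None = None) -> RuleSet:
    """Read a ``node<TAB>expression`` rule table into a :class:`RuleSet`."""
    from .network import BooleanRule

    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"node", "expression"}
    if not required.issubset(df.columns):
        raise TableFormatError(path, 1, f"expected columns {sorted(required)}")
    rules = {}
    for i, row in df.iterrows():
        try:
            rules[row["node"]] = BooleanRule(row["node"], parse_expression(row["expression"]))
        except ValueError as exc:
            raise TableFormatError(path, int(i) + 2, str(exc)) from exc
    return RuleSet(rules, clamps=clamps)


def write_rule_table(rules: RuleSet, path: str | Path):
    lines = ["node\texpression"]
    lines += [f"{n}\t{rules.rules[n].expression}" for n in rules.nodes]
    Path(path).write_text("\n".join(lines) + "\n")


def read_mutation_table(path: str | Path) -> MutationTable:
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(path, df, ["cell_line", "node", "effect"])
    return MutationTable([tuple(r) for r in df[["cell_line", "node", "effect"]].to_numpy()])


def write_mutation_table(table: MutationTable, path: str | Path):
    lines = ["cell_line\tnode\teffect"]
    lines += [f"{cl}\t{n}\t{eff}" for cl, n, eff in table.rows]
    Path(path).write_text("\n".join(lines) + "\n")


def read_override_table(path: str | Path) -> RuleOverrideTable:
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(path, df, ["cell_line", "node", "expression"])
    return RuleOverrideTable(
        [tuple(r) for r in df[["cell_line", "node", "expression"]].to_numpy()]
    )


def read_expression(path: str | Path) -> pd.DataFrame:
    """Genes x cell-lines matrix; first column holds gene names."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] < 1:
        raise TableFormatError(path, 1, "expression matrix has no cell line columns")
    return df


def write_expression(matrix: pd.DataFrame, path: str | Path):
    matrix.to_csv(path, sep="\t", index_label="gene")


def read_drug_table(path: str | Path) -> list[Drug]:
    """``drug<TAB>target<TAB>mode`` rows (one per target) into Drug objects."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(path, df, ["drug", "target", "mode"])
    drugs = []
    for name, group in df.groupby("drug", sort=False):
        drugs.append(
            Drug(name=str(name), targets=tuple(zip(group["target"], group["mode"])))
        )
    return drugs


def write_drug_table(drugs: Sequence[Drug], path: str | Path):
    lines = ["drug\ttarget\tmode"]
    for d in drugs:
        lines += [f"{d.name}\t{node}\t{mode}" for node, mode in d.targets]
    Path(path).write_text("\n".join(lines) + "\n")


def read_pair_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require_columns(path, df, ["drug_a", "drug_b", "cell_line", "observed_hsa"])
    return df


def write_pair_table(pairs: pd.DataFrame, path: str | Path):
    pairs.to_csv(path, sep="\t", index=False)


def read_role_table(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(path, df, ["node", "role"])
    return dict(zip(df["node"], df["role"]))


def write_role_table(roles: Mapping[str, str], path: str | Path):
    lines = ["node\trole"] + [f"{n}\t{r}" for n, r in roles.items()]
    Path(path).write_text("\n".join(lines) + "\n")


def write_activity_long(activity_rows: pd.DataFrame, path: str | Path):
    """Long-format activity export (pair, cell line, node, doseA, doseB, activity)."""
    activity_rows.to_csv(path, sep="\t", index=False)


def write_manifest(path: str | Path, **payload):
    Path(path).write_text(json.dumps(payload, indent=2, default=str) + "\n")


def write_scenario(scenario, out_dir: str | Path) -> Path:
    """Write a synthetic scenario as the standard bundle of delimited files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_network(scenario.network, out / "edges.tsv")
    write_rule_table(scenario.rules, out / "rules.tsv")
    write_expression(scenario.expression, out / "expression.tsv")
    write_mutation_table(scenario.mutations, out / "mutations.tsv")
    write_drug_table(scenario.drugs, out / "drugs.tsv")
    write_pair_table(scenario.pairs, out / "pairs.tsv")
    write_role_table(scenario.roles, out / "roles.tsv")
    write_manifest(
        out / "manifest.json",
        seed=scenario.seed,
        reporter=scenario.reporter,
        config=vars(scenario.config),
        n_nodes=len(scenario.network.nodes),
        n_edges=len(scenario.network.edges),
        n_pairs=len(scenario.pairs),
    )
    return out


def _require_columns(path, df: pd.DataFrame, columns: Sequence[str]):
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise TableFormatError(path, 1, f"missing column(s) {missing}")
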