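"""Reference packages: tree + alignment + taxonomy + model settings.

A reference package directory holds::

    tree.nwk        newick tree with branch lengths
    alignment.fasta reference amino-acid MSA (one row per tree leaf)
    taxonomy.tsv    optional; leaf <TAB> domain;phylum;...;species (7 ranks)
    config          flat key=value lines (model=WAG, alpha=..., name=...)

plus the jplace writer for placement results.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from .models import EMPIRICAL_MODELS
from .msa import MSA, MSAError
from .tree import ReferenceTree, TreeError, parse_newick, write_jplace_newick, write_newick

RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")
N_RANKS = len(RANKS)


class RefPackageError(ValueError):
    pass


@dataclass
class RefPackage:
    """The unit the placement pipeline consumes."""

    tree: ReferenceTree
    msa: MSA
    taxonomy: dict[str, tuple[str, ...]] | None = None
    model_name: str = "WAG"
    alpha: float | None = None  # None: estimate during reference fitting
    name: str = "refpkg"

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        leaves = self.tree.leaf_labels
        missing = [l for l in leaves if l not in self.msa]
        if missing:
            raise RefPackageError(f"MSA is missing rows for tree leaves: {missing}")
        if self.model_name.upper() not in EMPIRICAL_MODELS and self.model_name.upper() != "UNIFORM":
            raise RefPackageError(f"unknown model {self.model_name!r}")
        if self.taxonomy is not None:
            depths = {len(v) for v in self.taxonomy.values()}
            if depths != {N_RANKS}:
                raise RefPackageError(
                    f"taxonomy lineages must all have {N_RANKS} ranks, found depths {sorted(depths)}"
                )
            absent = [l for l in leaves if l not in self.taxonomy]
            if absent:
                raise RefPackageError(f"taxonomy missing for leaves: {absent}")

    @property
    def n_cols(self) -> int:
        return self.msa.n_cols


def read_taxonomy(path) -> dict[str, tuple[str, ...]]:
    out: dict[str, tuple[str, ...]] = {}
    for ln in Path(path).read_text().splitlines():
        if not ln.strip() or ln.startswith("#"):
            continue
        parts = ln.rstrip("\n").split("\t")
        if len(parts) != 2:
            raise RefPackageError(f"taxonomy line needs 2 tab-separated fields: {ln!r}")
        label, lineage = parts
        if label in out:
            raise RefPackageError(f"duplicate taxonomy entry for {label!r}")
        out[label] = tuple(x.strip() for x in lineage.split(";"))
    return out


def write_taxonomy(taxonomy: dict[str, tuple[str, ...]], path) -> None:
    with open(path, "w") as fh:
        for label, lineage in taxonomy.items():
            fh.write(f"{label}\t{';'.join(lineage)}\n")


def _read_config(path) -> dict[str, str]:
    cfg = {}
    for ln in Path(path).read_text().splitlines():
        ln = ln.strip()
        if not ln or ln.startswith("#"):
            continue
        if "=" not in ln:
            raise RefPackageError(f"config line must be key=value: {ln!r}")
        k, v = ln.split("=", 1)
        cfg[k.strip()] = v.strip()
    return cfg


def load_reference_package(directory) -> RefPackage:
    d = Path(directory)
    if not d.is_dir():
        raise RefPackageError(f"not a reference package directory: {d}")
    try:
        tree = parse_newick((d / "tree.nwk").read_text())
        msa = MSA.from_fasta(str(d / "alignment.fasta"))
    except FileNotFoundError as exc:
        raise RefPackageError(f"incomplete reference package: {exc}") from exc
    except (TreeError, MSAError) as exc:
        raise RefPackageError(str(exc)) from exc
    taxonomy = None
    if (d / "taxonomy.tsv").exists():
        taxonomy = read_taxonomy(d / "taxonomy.tsv")
    cfg = _read_config(d / "config") if (d / "config").exists() else {}
    alpha = float(cfg["alpha"]) if "alpha" in cfg else None
    return RefPackage(
        tree=tree,
        msa=msa,
        taxonomy=taxonomy,
        model_name=cfg.get("model", "WAG"),
        alpha=alpha,
        name=cfg.get("name", d.name),
    )


def save_reference_package(pkg: RefPackage, directory) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    (d / "tree.nwk").write_text(write_newick(pkg.tree) + "\n")
    pkg.msa.to_fasta(d / "alignment.fasta")
    if pkg.taxonomy is not None:
        write_taxonomy(pkg.taxonomy, d / "taxonomy.tsv")
    lines = [f"name={pkg.name}", f"model={pkg.model_name}"]
    if pkg.alpha is not None:
        lines.append(f"alpha={pkg.alpha:.10g}")
    (d / "config").write_text("\n".join(lines) + "\n")


# ----------------------------------------------------------------------
# jplace v3 output


def write_jplace(results, tree: ReferenceTree, path=None) -> dict:
    """Serialize placement results as a jplace v3 document.

    Each result contributes one pquery whose fields are
    [edge_num, likelihood, like_weight_ratio, distal_length,
    pendant_length]; edge numbers are the tree's stable branch ids and
    like_weight_ratios per query sum to 1 over the reported placements.
    """
    valid = {n.edge_id for n in tree.edge_nodes}
    pqueries = []
    for res in results:
        rows = []
        lwr_total = 0.0
        for pl in res.reported_placements():
            if pl.edge_id not in valid:
                raise RefPackageError(f"placement references unknown branch id {pl.edge_id}")
            rows.append(
                [
                    int(pl.edge_id),
                    float(pl.log_likelihood),
                    float(pl.like_weight_ratio),
                    float(pl.distal_length),
                    float(pl.pendant_length),
                ]
            )
            lwr_total += pl.like_weight_ratio
        if rows and lwr_total > 0:
            for r in rows:
                r[2] /= lwr_total
        pqueries.append({"p": rows, "n": [res.query_id]})
    doc = {
        "version": 3,
        "tree": write_jplace_newick(tree),
        "fields": [
            "edge_num",
            "likelihood",
            "like_weight_ratio",
            "distal_length",
            "pendant_length",
        ],
        "placements": pqueries,
        "metadata": {"software": "phyloplace"},
    }
    if path is not None:
        Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True) + "\n")
    return doc
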