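"""Shared domain types and tabular/tree/report readers and writers.

The observational unit is the *spot*: a microdissected region of 2-5
adjacent tumor glands, assumed clonal.  Spots carry section-plane
coordinates (mm, arbitrary per-slide origin), a pathologist phenotype
label (S = superficial, I = invasive, M = metastatic) and a sampling
site.  Per spot and per panel locus we store the variant allele
frequency (VAF = alt reads / total reads) and the read depth.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import yaml

PHENOTYPES = ("S", "I", "M")
SITES = ("primary", "lymph_node", "distant")

__all__ = [
    "Locus",
    "SpotRecord",
    "VAFMatrix",
    "PipelineConfig",
    "StudySummaryRow",
    "CloneTree",
    "read_vaf_table",
    "write_vaf_table",
    "newick_string",
    "write_newick",
    "read_newick",
    "load_study_summary",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Locus:
    """One assayed somatic-variant position of a tumor-specific panel."""

    locus_id: str
    gene_label: str | None = None
    is_driver: bool = False


@dataclass(frozen=True)
class SpotRecord:
    """Metadata for one microdissected spot.

    ``phenotype`` may be ``None`` only for spots excluded from
    phylogeography; such spots still participate in genotyping.
    Coordinates are section-plane millimetres with arbitrary per-slide
    origin; only within-slide pairwise distances are meaningful.
    """

    spot_id: str
    tumor_id: str
    slide_id: str
    x_mm: float = math.nan
    y_mm: float = math.nan
    phenotype: str | None = None
    site: str = "primary"

    def __post_init__(self) -> None:
        if self.phenotype is not None and self.phenotype not in PHENOTYPES:
            raise ValueError(f"unknown phenotype {self.phenotype!r} for spot {self.spot_id}")
        if self.site not in SITES:
            raise ValueError(f"unknown site {self.site!r} for spot {self.spot_id}")
        if (self.phenotype == "M") != (self.site != "primary"):
            raise ValueError(
                f"spot {self.spot_id}: phenotype M is required exactly for "
                f"non-primary sites (got phenotype={self.phenotype}, site={self.site})"
            )

    @property
    def is_primary(self) -> bool:
        return self.site == "primary"


class VAFMatrix:
    """Spot x locus variant-allele fractions with read depths.

    ``vaf`` is NaN wherever ``depth`` is zero (no observation).
    """

    def __init__(
        self,
        spots: Sequence[SpotRecord],
        loci: Sequence[Locus],
        vaf: np.ndarray,
        depth: np.ndarray,
    ) -> None:
        self.spots = list(spots)
        self.loci = list(loci)
        self.vaf = np.asarray(vaf, dtype=float)
        self.depth = np.asarray(depth, dtype=np.int64)
        n_s, n_l = len(self.spots), len(self.loci)
        if self.vaf.shape != (n_s, n_l) or self.depth.shape != (n_s, n_l):
            raise ValueError(
                f"shape mismatch: {n_s} spots x {n_l} loci vs vaf {self.vaf.shape}, "
                f"depth {self.depth.shape}"
            )
        if np.any(self.depth < 0):
            raise ValueError("negative read depths")
        ids = [s.spot_id for s in self.spots]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate spot ids")
        lids = [l.locus_id for l in self.loci]
        if len(set(lids)) != len(lids):
            raise ValueError("duplicate locus ids")
        # vaf defined only where depth > 0
        self.vaf = np.where(self.depth > 0, self.vaf, np.nan)
        with np.errstate(invalid="ignore"):
            bad = (self.vaf < 0) | (self.vaf > 1)
        if np.any(bad):
            raise ValueError("VAF outside [0, 1]")

    # -- indexing helpers --------------------------------------------------
    @property
    def spot_ids(self) -> list[str]:
        return [s.spot_id for s in self.spots]

    @property
    def locus_ids(self) -> list[str]:
        return [l.locus_id for l in self.loci]

    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.spots), len(self.loci))

    def spot_index(self, spot_id: str) -> int:
        return self.spot_ids.index(spot_id)

    def locus_index(self, locus_id: str) -> int:
        return self.locus_ids.index(locus_id)

    def subset_spots(self, keep: Iterable[str]) -> "VAFMatrix":
        keep = set(keep)
        idx = [i for i, s in enumerate(self.spots) if s.spot_id in keep]
        return VAFMatrix(
            [self.spots[i] for i in idx], self.loci, self.vaf[idx, :], self.depth[idx, :]
        )

    def to_long_frame(self) -> pd.DataFrame:
        rows = []
        for i, s in enumerate(self.spots):
            for j, l in enumerate(self.loci):
                d = int(self.depth[i, j])
                v = self.vaf[i, j]
                alt = int(round(v * d)) if d > 0 else 0
                rows.append((s.spot_id, l.locus_id, d - alt, alt))
        return pd.DataFrame(rows, columns=["spot_id", "locus_id", "ref_reads", "alt_reads"])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, VAFMatrix):
            return NotImplemented
        return (
            self.spots == other.spots
            and self.loci == other.loci
            and np.array_equal(self.depth, other.depth)
            and np.allclose(self.vaf, other.vaf, equal_nan=True)
        )


@dataclass
class PipelineConfig:
    """Tunable thresholds of the genotyping/phylogeography pipeline.

    Defaults follow standard deep-targeted-resequencing practice for
    clonal spots: a 5% VAF call threshold, 20-read minimum depth, a 6%
    singleton-noise cutoff, promotion of >90%-prevalent mutations to
    public, 1000 bootstrap replicates and an early/late split at half
    the root-to-tip height.
    """

    vaf_call_threshold: float = 0.05
    min_depth: int = 20
    singleton_noise_vaf: float = 0.06
    public_promotion_fraction: float = 0.90
    bootstrap_n: int = 1000
    early_late_cutoff: float = 0.5
    rng_seed: int = 0
    # secondary knobs
    max_missing_fraction: float = 0.30   # spot exclusion cutoff
    homoplasy_flip_budget: float = 0.05  # max flips as fraction of cells
    adjacency_radius_mm: float = 4.0     # spot adjacency for contiguity
    root_distance_metric: str = "mutations"  # or "nodes"

    def __post_init__(self) -> None:
        if not (0 < self.vaf_call_threshold < self.singleton_noise_vaf < 0.5):
            raise ValueError(
                "need 0 < vaf_call_threshold < singleton_noise_vaf < 0.5"
            )
        if not (0.5 < self.public_promotion_fraction < 1):
            raise ValueError("public_promotion_fraction must be in (0.5, 1)")
        if self.min_depth < 0 or self.bootstrap_n < 1:
            raise ValueError("min_depth >= 0 and bootstrap_n >= 1 required")
        if self.root_distance_metric not in ("mutations", "nodes"):
            raise ValueError("root_distance_metric must be 'mutations' or 'nodes'")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)  # YAML superset covers JSON
        return cls(**data)

    def with_seed(self, seed: int) -> "PipelineConfig":
        return replace(self, rng_seed=seed)


@dataclass(frozen=True)
class StudySummaryRow:
    """One tumor's row of the study-level census."""

    tumor_id: str
    n_spots: int
    n_loci: int
    n_subclones: int
    pheno_s: int
    pheno_i: int
    pheno_si: int
    monophyletic_inv: str  # yes / no / NA
    early_inv: str
    multiclonal_inv: str
    n_invasion_events: int | None
    is_carcinoma: bool

    def __post_init__(self) -> None:
        if self.pheno_s + self.pheno_i + self.pheno_si > self.n_subclones:
            raise ValueError(
                f"tumor {self.tumor_id}: primary phenotype tallies exceed subclone count"
            )
        for fld in ("monophyletic_inv", "early_inv", "multiclonal_inv"):
            if getattr(self, fld) not in ("yes", "no", "NA"):
                raise ValueError(f"tumor {self.tumor_id}: {fld} must be yes/no/NA")


# ---------------------------------------------------------------------------
# Clone trees
# ---------------------------------------------------------------------------

GERMLINE = "germline"


class CloneTree:
    """Rooted tree over subclones with mutation sets on branches.

    The root is the germline (all-absent genotype).  Tips are subclones;
    an observed genotype identical to an inferred internal node is
    attached as a zero-length tip branch.  Each mutation appears on
    exactly one edge (homoplasy-free), so the union of branch mutation
    sets along the root-to-tip path equals the tip's genotype.
    """

    def __init__(self, graph: nx.DiGraph, root: str = GERMLINE) -> None:
        self.graph = graph
        self.root = root
        if root not in graph:
            raise ValueError("root missing from graph")
        for u, v in graph.edges:
            graph.edges[u, v].setdefault("mutations", frozenset())

    # -- structure ---------------------------------------------------------
    def tips(self) -> list[str]:
        """Leaf node names (= subclone ids)."""
        return sorted(n for n in self.graph if self.graph.out_degree(n) == 0)

    def parent(self, node: str) -> str | None:
        preds = list(self.graph.predecessors(node))
        return preds[0] if preds else None

    def children(self, node: str) -> list[str]:
        return sorted(self.graph.successors(node))

    def edge_mutations(self, u: str, v: str) -> frozenset:
        return self.graph.edges[u, v]["mutations"]

    def branch_length(self, u: str, v: str) -> int:
        return len(self.edge_mutations(u, v))

    def path_to_root(self, node: str) -> list[str]:
        path = [node]
        while (p := self.parent(path[-1])) is not None:
            path.append(p)
        return path[::-1]

    def genotype_of(self, node: str) -> frozenset:
        """Union of mutation sets on the root-to-node path."""
        muts: set = set()
        path = self.path_to_root(node)
        for u, v in zip(path, path[1:]):
            muts |= self.edge_mutations(u, v)
        return frozenset(muts)

    def root_distance(self, node: str, metric: str = "mutations") -> int:
        """Mutations (or internal nodes) between root and ``node``."""
        path = self.path_to_root(node)
        if metric == "mutations":
            return sum(self.branch_length(u, v) for u, v in zip(path, path[1:]))
        if metric == "nodes":
            return len(path) - 1
        raise ValueError(f"unknown metric {metric!r}")

    def clade_tips(self, node: str) -> frozenset:
        return frozenset(
            n for n in nx.descendants(self.graph, node) | {node}
            if self.graph.out_degree(n) == 0
        )

    def mrca(self, tips: Iterable[str]) -> str:
        tips = list(tips)
        paths = [self.path_to_root(t) for t in tips]
        mrca = self.root
        for nodes in zip(*paths):
            if len(set(nodes)) == 1:
                mrca = nodes[0]
            else:
                break
        return mrca

    def tip_bipartitions(self) -> dict[tuple[str, str], frozenset]:
        """Tip set below each internal edge (root edge excluded)."""
        out = {}
        for u, v in self.graph.edges:
            if self.graph.out_degree(v) == 0:
                continue  # tip edge
            out[(u, v)] = self.clade_tips(v)
        return out

    def internal_nodes_between(self, tip_a: str, tip_b: str) -> int:
        """Number of internal nodes on the path joining two tips."""
        if tip_a == tip_b:
            raise ValueError("identical tips")
        ug = self.graph.to_undirected(as_view=True)
        path = nx.shortest_path(ug, tip_a, tip_b)
        return len(path) - 2

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CloneTree):
            return NotImplemented
        return self.tip_genotype_map() == other.tip_genotype_map()

    def tip_genotype_map(self) -> dict[str, frozenset]:
        return {t: self.genotype_of(t) for t in self.tips()}

    def isomorphic_to(self, other: "CloneTree") -> bool:
        """Same tips, same genotypes, same tip bipartitions."""
        if set(self.tips()) != set(other.tips()):
            return False
        if self.tip_genotype_map() != other.tip_genotype_map():
            return False
        mine = {b for b in self.tip_bipartitions().values() if 1 < len(b) < len(self.tips())}
        theirs = {b for b in other.tip_bipartitions().values() if 1 < len(b) < len(other.tips())}
        return mine == theirs


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

_META_COLS = ["spot_id", "tumor_id", "slide_id", "x_mm", "y_mm", "phenotype", "site"]


def _read_metadata(metadata_path: str | Path) -> dict[str, SpotRecord]:
    meta = pd.read_csv(metadata_path, sep="\t", dtype=str, comment="#")
    missing = [c for c in ("spot_id", "tumor_id", "slide_id") if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata missing columns: {missing}")
    records = {}
    for _, row in meta.iterrows():
        sid = row["spot_id"]
        if sid in records:
            raise ValueError(f"duplicate metadata row for spot {sid}")
        pheno = row.get("phenotype")
        if pd.isna(pheno) or pheno == "":
            pheno = None
        site = row.get("site")
        if pd.isna(site) or site == "" or site is None:
            site = "primary"
        def _coord(key: str) -> float:
            val = row.get(key)
            return float(val) if val not in (None, "") and not pd.isna(val) else math.nan
        records[sid] = SpotRecord(
            spot_id=sid,
            tumor_id=row["tumor_id"],
            slide_id=row["slide_id"],
            x_mm=_coord("x_mm"),
            y_mm=_coord("y_mm"),
            phenotype=pheno,
            site=site,
        )
    return records


def read_vaf_table(path: str | Path, metadata_path: str | Path) -> VAFMatrix:
    """Read a spot-by-locus VAF/depth table plus spot metadata.

    Two TSV dialects are auto-detected from the header:

    * long — columns ``spot_id, locus_id, ref_reads, alt_reads``;
    * wide — first column ``spot_id``, remaining columns are locus ids,
      cells are ``alt:depth``.
    """
    head = pd.read_csv(path, sep="\t", nrows=0, comment="#")
    cols = list(head.columns)
    if cols[:4] == ["spot_id", "locus_id", "ref_reads", "alt_reads"]:
        df = pd.read_csv(path, sep="\t", comment="#", dtype={"spot_id": str, "locus_id": str})
        if df.duplicated(["spot_id", "locus_id"]).any():
            dup = df[df.duplicated(["spot_id", "locus_id"])].iloc[0]
            raise ValueError(f"duplicate (spot, locus) pair: ({dup.spot_id}, {dup.locus_id})")
        if (df.ref_reads < 0).any() or (df.alt_reads < 0).any():
            raise ValueError("negative read counts")
        spot_ids = list(dict.fromkeys(df.spot_id))
        locus_ids = list(dict.fromkeys(df.locus_id))
        alt = df.pivot(index="spot_id", columns="locus_id", values="alt_reads") \
                .reindex(index=spot_ids, columns=locus_ids).fillna(0).to_numpy()
        ref = df.pivot(index="spot_id", columns="locus_id", values="ref_reads") \
                .reindex(index=spot_ids, columns=locus_ids).fillna(0).to_numpy()
    elif cols and cols[0] == "spot_id":
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str).set_index("spot_id")
        spot_ids = list(df.index)
        locus_ids = list(df.columns)
        if len(set(spot_ids)) != len(spot_ids):
            dups = pd.Series(spot_ids)
            dup = dups[dups.duplicated()].iloc[0]
            raise ValueError(f"duplicate (spot, locus) pair: spot {dup} repeated")
        alt = np.zeros((len(spot_ids), len(locus_ids)))
        dep = np.zeros_like(alt)
        for i, sid in enumerate(spot_ids):
            for j, lid in enumerate(locus_ids):
                a_s, d_s = str(df.iloc[i, j]).split(":")
                a, d = int(a_s), int(d_s)
                if a < 0 or d < 0 or a > d:
                    raise ValueError(f"bad cell {a}:{d} at ({sid}, {lid})")
                alt[i, j], dep[i, j] = a, d
        ref = dep - alt
    else:
        raise ValueError(f"unrecognized VAF table header: {cols[:5]}")

    depth = (alt + ref).astype(np.int64)
    with np.errstate(divide="ignore", invalid="ignore"):
        vaf = np.where(depth > 0, alt / np.maximum(depth, 1), np.nan)

    records = _read_metadata(metadata_path)
    missing_meta = [s for s in spot_ids if s not in records]
    if missing_meta:
        raise ValueError(f"spots missing metadata: {missing_meta}")
    spots = [records[s] for s in spot_ids]
    loci = [Locus(lid) for lid in locus_ids]
    return VAFMatrix(spots, loci, vaf, depth)


def write_vaf_table(
    vm: VAFMatrix,
    path: str | Path,
    metadata_path: str | Path,
    dialect: str = "long",
) -> None:
    """Write a VAFMatrix in either TSV dialect, plus its metadata table."""
    if dialect == "long":
        vm.to_long_frame().to_csv(path, sep="\t", index=False)
    elif dialect == "wide":
        with open(path, "w") as fh:
            fh.write("spot_id\t" + "\t".join(vm.locus_ids) + "\n")
            for i, sid in enumerate(vm.spot_ids):
                cells = []
                for j in range(len(vm.loci)):
                    d = int(vm.depth[i, j])
                    a = int(round(vm.vaf[i, j] * d)) if d > 0 else 0
                    cells.append(f"{a}:{d}")
                fh.write(sid + "\t" + "\t".join(cells) + "\n")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    rows = [
        {
            "spot_id": s.spot_id, "tumor_id": s.tumor_id, "slide_id": s.slide_id,
            "x_mm": s.x_mm, "y_mm": s.y_mm,
            "phenotype": s.phenotype or "", "site": s.site,
        }
        for s in vm.spots
    ]
    pd.DataFrame(rows, columns=_META_COLS).to_csv(metadata_path, sep="\t", index=False)


def _newick_label(name: str) -> str:
    if any(c in name for c in " ()[]':;,"):
        return "'" + name.replace("'", "''") + "'"
    return name


def newick_string(tree: CloneTree, support: Mapping | None = None) -> str:
    """Render a CloneTree as Newick.

    Tip labels are subclone ids, branch lengths are mutation counts and
    the germline root carries its label.  Optional bootstrap supports
    (keyed by internal edge ``(u, v)``) become internal-node labels.
    """
    for tip in tree.tips():
        if not tip:
            raise ValueError("unlabeled tip")

    def render(node: str) -> str:
        kids = tree.children(node)
        if not kids:
            return _newick_label(node)
        parts = []
        for child in kids:
            sub = render(child)
            parts.append(f"{sub}:{tree.branch_length(node, child)}")
        label = ""
        if node == tree.root:
            label = _newick_label(tree.root)
        elif support is not None:
            parent = tree.parent(node)
            if parent is not None and (parent, node) in support:
                label = f"{support[(parent, node)]:.3f}"
        return "(" + ",".join(parts) + ")" + label

    return render(tree.root) + ";"


def write_newick(tree: CloneTree, path: str | Path, support: Mapping | None = None) -> None:
    """Write :func:`newick_string` output to a file."""
    Path(path).write_text(newick_string(tree, support) + "\n")


def read_newick(path: str | Path):
    """Parse a Newick file into a dendropy Tree (for round-trip checks)."""
    import dendropy

    return dendropy.Tree.get(path=str(path), schema="newick")


# ---------------------------------------------------------------------------
# Study-summary fixture (census table)
# ---------------------------------------------------------------------------

_SUMMARY_COLS = [
    "tumor_id", "n_spots", "n_loci", "n_subclones", "pheno_s", "pheno_i",
    "pheno_si", "monophyletic_inv", "early_inv", "multiclonal_inv",
    "n_invasion_events", "is_carcinoma",
]


def load_study_summary(path: str | Path | None = None) -> list[StudySummaryRow]:
    """Load the per-tumor census table (default: the packaged study table)."""
    if path is None:
        ref = resources.files("phylogeo").joinpath("data/study_summary.tsv")
        with resources.as_file(ref) as p:
            return load_study_summary(p)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    missing = [c for c in _SUMMARY_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"study summary missing columns: {missing}")
    rows = []
    for _, r in df.iterrows():
        ev = r["n_invasion_events"]
        rows.append(
            StudySummaryRow(
                tumor_id=r["tumor_id"],
                n_spots=int(r["n_spots"]),
                n_loci=int(r["n_loci"]),
                n_subclones=int(r["n_subclones"]),
                pheno_s=int(r["pheno_s"]),
                pheno_i=int(r["pheno_i"]),
                pheno_si=int(r["pheno_si"]),
                monophyletic_inv=r["monophyletic_inv"],
                early_inv=r["early_inv"],
                multiclonal_inv=r["multiclonal_inv"],
                n_invasion_events=None if pd.isna(ev) or ev == "" else int(ev),
                is_carcinoma=r["is_carcinoma"].strip().lower() in ("true", "yes", "1"),
            )
        )
    return rows


def write_report_json(report: Mapping, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")


def read_report_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
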