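"""Merging the clone tree with spot phenotypes: the phylogeography of invasion.

Spots are labelled superficial (S, above the muscularis mucosae),
invasive (I, below it) or metastatic (M, non-primary sites).  Under the
irreversible-migration assumption — cells migrate from superficial to
invasive regions but never back — the minimal number of
superficial-to-invasive transitions consistent with the tree and the
tip phenotypes counts the invasion events.  A mixed (S-I) subclone
proves an invasion within that tip's own lineage; a clade of purely
invasive tips can be explained by a single ancestral crossing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Mapping, Sequence

from .datamodel import CloneTree, Locus, PipelineConfig
from .genotyping import Subclone

__all__ = [
    "SubclonePhenotype",
    "InvasionReport",
    "TimingClass",
    "MetastasisDivergence",
    "assign_subclone_phenotypes",
    "invasion_monophyly",
    "count_invasion_events",
    "invasion_event_oracle",
    "classify_timing",
    "compare_metastasis_genotype",
]


@dataclass(frozen=True)
class SubclonePhenotype:
    """Phenotype class of a subclone over its primary-tumor member spots.

    ``pclass`` is None for metastasis-only subclones (excluded from the
    primary S/I/S-I tallies).
    """

    subclone_id: str
    pclass: str | None  # "S" | "I" | "S-I" | None
    has_metastatic_member: bool

    @property
    def invading(self) -> bool:
        return self.pclass in ("I", "S-I") or self.has_metastatic_member


@dataclass
class TimingClass:
    subclone_id: str
    relative_root_distance: float
    timing: str  # "early" | "late"


@dataclass
class InvasionReport:
    tumor_id: str
    invading_subclones: list[str]
    monophyletic: bool | None
    n_events: int
    early_invasion: bool
    per_event: list[dict] = field(default_factory=list)
    timing: list[TimingClass] = field(default_factory=list)


@dataclass
class MetastasisDivergence:
    identical_across_met: bool
    private_carried: int
    public_missing: int
    drivers_missing: list[str]

    @property
    def early_divergence(self) -> bool:
        return self.private_carried == 0


# ---------------------------------------------------------------------------
# Phenotype assignment
# ---------------------------------------------------------------------------

def assign_subclone_phenotypes(subclones: Sequence[Subclone]) -> list[SubclonePhenotype]:
    """Classify each subclone as S, I or S-I over its primary spots."""
    out = []
    for sc in subclones:
        primary = [s for s in sc.member_spots if s.is_primary]
        has_met = any(not s.is_primary for s in sc.member_spots)
        for s in primary:
            if s.phenotype not in ("S", "I"):
                raise ValueError(
                    f"primary spot {s.spot_id} of subclone {sc.subclone_id} "
                    f"has no S/I phenotype label"
                )
        if not primary:
            pclass = None
        else:
            phenos = {s.phenotype for s in primary}
            pclass = "S-I" if phenos == {"S", "I"} else phenos.pop()
        out.append(SubclonePhenotype(sc.subclone_id, pclass, has_met))
    return out


def _tip_states(phenotypes: Sequence[SubclonePhenotype]) -> dict[str, str]:
    """Effective per-tip state for event counting.

    Metastatic membership counts as invaded; a primary-S subclone with a
    metastatic member therefore behaves like S-I (its lineage is present
    superficially and has its own crossing), and a metastasis-only
    subclone behaves like I.
    """
    states = {}
    for ph in phenotypes:
        if ph.pclass == "S":
            states[ph.subclone_id] = "S-I" if ph.has_metastatic_member else "S"
        elif ph.pclass == "I" or ph.pclass is None and ph.has_metastatic_member:
            states[ph.subclone_id] = "I"
        elif ph.pclass == "S-I":
            states[ph.subclone_id] = "S-I"
        elif ph.pclass is None:
            states[ph.subclone_id] = "S"  # unreachable for valid inputs
    return states


# ---------------------------------------------------------------------------
# Monophyly
# ---------------------------------------------------------------------------

def invasion_monophyly(
    tree: CloneTree, phenotypes: Sequence[SubclonePhenotype]
) -> bool | None:
    """Do the invading subclones form a single clade free of pure-S tips?

    None when no subclone invades; a single invading subclone is
    monophyletic by convention.  Polyphyly of the invading subclones is
    the tree fingerprint of multiclonal invasion.
    """
    invading = [ph.subclone_id for ph in phenotypes if ph.invading]
    if not invading:
        return None
    if len(invading) == 1:
        return True
    mrca = tree.mrca(invading)
    clade = tree.clade_tips(mrca)
    by_id = {ph.subclone_id: ph for ph in phenotypes}
    for tip in clade:
        ph = by_id.get(tip)
        if ph is not None and not ph.invading:
            return False
    return True


# ---------------------------------------------------------------------------
# Invasion-event counting
# ---------------------------------------------------------------------------

def count_invasion_events(
    tree: CloneTree,
    phenotypes: Sequence[SubclonePhenotype],
    cfg: PipelineConfig | None = None,
    tumor_id: str = "",
) -> InvasionReport:
    """Minimal superficial-to-invasive transition count under irreversibility.

    Every S-I tip forces one crossing within its own lineage (its parent
    lineage stayed superficial); the purely invasive tips are covered by
    one crossing per maximal all-invasive clade.  Hence

        n_events = (# S-I tips) + (# maximal clades of all-I tips).
    """
    cfg = cfg or PipelineConfig()
    states = _tip_states(phenotypes)
    invading = sorted(ph.subclone_id for ph in phenotypes if ph.invading)
    per_event: list[dict] = []

    for tip, st in states.items():
        if st == "S-I":
            per_event.append({"kind": "tip", "subclones": [tip]})

    def walk(node: str) -> None:
        tips_below = tree.clade_tips(node)
        if all(states.get(t) == "I" for t in tips_below):
            per_event.append({"kind": "clade", "subclones": sorted(tips_below)})
            return
        for child in tree.children(node):
            walk(child)

    if any(st == "I" for st in states.values()):
        walk(tree.root)

    n_events = len(per_event)
    if not invading:
        import warnings

        warnings.warn(f"tumor {tumor_id or '?'}: no invading subclones; "
                      "0 invasion events (adenoma-like)", stacklevel=2)

    timing = classify_timing(tree, cfg)
    timing_by_id = {t.subclone_id: t for t in timing}
    early_inv = any(
        timing_by_id[s].timing == "early" for s in invading if s in timing_by_id
    )
    return InvasionReport(
        tumor_id=tumor_id,
        invading_subclones=invading,
        monophyletic=invasion_monophyly(tree, phenotypes),
        n_events=n_events,
        early_invasion=early_inv,
        per_event=sorted(per_event, key=lambda e: (e["kind"], e["subclones"])),
        timing=timing,
    )


def invasion_event_oracle(
    tree: CloneTree, phenotypes: Sequence[SubclonePhenotype]
) -> int:
    """Brute-force minimum invasion count by state enumeration (<= 12 tips).

    Each tree node is assigned superficial or invaded; the root is
    superficial, invaded nodes only have invaded descendants, I tips
    must be invaded, S and S-I tips superficial.  Transitions are
    counted on edges, plus one forced within-tip event per S-I tip.
    """
    states = _tip_states(phenotypes)
    tips = tree.tips()
    if len(tips) > 12:
        raise ValueError("oracle limited to 12 tips")
    internal = [n for n in tree.graph if tree.graph.out_degree(n) > 0 and n != tree.root]
    forced_tip_events = sum(1 for t in tips if states.get(t) == "S-I")

    fixed = {tree.root: 0}
    for t in tips:
        fixed[t] = 1 if states.get(t) == "I" else 0

    best = None
    for combo in product((0, 1), repeat=len(internal)):
        assign = dict(fixed)
        assign.update(zip(internal, combo))
        ok = True
        transitions = 0
        for u, v in tree.graph.edges:
            if assign[u] == 1 and assign[v] == 0:
                ok = False  # invaded lineage cannot return superficial
                break
            if assign[u] == 0 and assign[v] == 1:
                transitions += 1
        if ok and (best is None or transitions < best):
            best = transitions
    assert best is not None
    return best + forced_tip_events


# ---------------------------------------------------------------------------
# Early / late timing
# ---------------------------------------------------------------------------

def classify_timing(tree: CloneTree, cfg: PipelineConfig | None = None) -> list[TimingClass]:
    """Early/late split by relative root distance of each tip's attachment.

    A subclone arose where its branch attaches to the tree; its relative
    root distance is that node's mutation count from the root divided by
    the maximum root-to-tip mutation count.  Early iff at or below the
    cutoff (default: the first half of tumorigenesis).
    """
    cfg = cfg or PipelineConfig()
    metric = cfg.root_distance_metric
    tips = tree.tips()
    denom = max((tree.root_distance(t, metric) for t in tips), default=0)
    out = []
    for t in sorted(tips):
        parent = tree.parent(t)
        dist = tree.root_distance(parent, metric) if parent is not None else 0
        rel = dist / denom if denom > 0 else 0.0
        out.append(TimingClass(t, rel, "early" if rel <= cfg.early_late_cutoff else "late"))
    return out


# ---------------------------------------------------------------------------
# Metastasis divergence
# ---------------------------------------------------------------------------

def compare_metastasis_genotype(
    met_subclones: Sequence[Subclone],
    primary_subclones: Sequence[Subclone],
    scope: Mapping[str, str],
    loci: Sequence[Locus] | None = None,
) -> MetastasisDivergence:
    """Compare metastatic genotypes against the primary tumor.

    Early divergence is signalled by metastases carrying none of the
    primary's private mutations; missing public mutations indicate
    divergence before the primary's most recent complete sweep.
    """
    if not met_subclones:
        raise ValueError("no metastatic subclones")
    genotypes = {sc.genotype for sc in met_subclones}
    identical = len(genotypes) == 1
    met = met_subclones[0]

    n_loci = len(met.genotype)
    locus_ids = [loci[j].locus_id if loci else f"L{j}" for j in range(n_loci)]
    public_idx = [j for j in range(n_loci) if scope.get(locus_ids[j]) == "public"]
    private_idx = [j for j in range(n_loci) if scope.get(locus_ids[j]) == "private"]

    primary_private = set()
    for sc in primary_subclones:
        for j in private_idx:
            if sc.genotype[j]:
                primary_private.add(j)

    private_carried = sum(1 for j in primary_private if met.genotype[j])
    public_missing = sum(1 for j in public_idx if not met.genotype[j])
    drivers_missing = []
    if loci is not None:
        drivers_missing = [
            loci[j].locus_id for j in public_idx
            if loci[j].is_driver and not met.genotype[j]
        ]
    return MetastasisDivergence(identical, private_carried, public_missing, drivers_missing)
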