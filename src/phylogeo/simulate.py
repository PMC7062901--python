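"""Spatial gland-fission tumor-section simulator with ground truth.

A tumor section is a 2D lattice of glands growing by Eden-style fission
from a single founder above the muscularis mucosae (MM).  Daughters
inherit their parent's mutations plus Poisson-distributed new ones
drawn from a finite targeted panel (infinite-sites restricted to the
panel, so the truth is homoplasy-free).  Crossing the MM downward is
gated by the growth mode:

* ``bottleneck`` — only lineages that accumulated the required number
  of private driver mutations may cross (a late, fitter subclone);
* ``multiclonal`` — any boundary fission may cross with a small
  probability from the start (branching growth with minimal barriers).

Each permitted crossing is logged as a ground-truth invasion event and
all glands below the MM trace to exactly one such event.  Spots of 2-5
adjacent glands are sampled and sequenced in silico at ~9000x with
binomial read noise; a clonal heterozygous mutation sits at
VAF = 0.5 x cellularity.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .datamodel import Locus, SpotRecord, VAFMatrix

__all__ = [
    "SimConfig",
    "Gland",
    "InvasionEvent",
    "SimTruth",
    "SimOutput",
    "simulate_tumor",
    "sample_spots",
    "emit_vaf_reads",
    "make_worked_fixture",
]

ERROR_FLOOR = 0.001  # sequencing-error alt-read fraction for absent loci


@dataclass
class SimConfig:
    """Growth, sampling and sequencing parameters of the simulator."""

    mode: str = "multiclonal"            # or "bottleneck"
    width: int = 40                      # lattice width (gland units)
    depth: int = 30                      # lattice depth (gland units)
    mm_depth: int = 15                   # row index of the muscularis mucosae
    mutation_rate: float = 0.06          # new panel mutations per fission (Poisson)
    panel_size: int = 50                 # targeted panel loci
    n_public: int = 8                    # founder (public) mutations
    target_glands: int = 450
    mixing_prob: float = 0.05            # early-dispersal probability per fission
    mixing_radius: int = 3               # dispersal radius (Chebyshev, gland units)
    invasion_prob: float = 0.05          # multiclonal: P(cross MM) per boundary fission
    n_drivers_required: int = 1          # bottleneck: private drivers needed to cross
    driver_prob: float = 0.12            # P(new mutation is a driver)
    n_spots: int = 16
    glands_per_spot: int = 3             # 2-5 in the emulated study
    min_spot_separation: float = 2.0     # lattice units between spot centers
    depth_mean: float = 9000.0           # mean read depth
    cellularity: float = 0.95
    met_divergence_time: float | None = None  # fraction of divisions; ~0.1 = early
    noise_free: bool = False             # deterministic read counts (depth->inf surrogate)
    lattice_mm: float = 0.5              # physical gland spacing in mm
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("bottleneck", "multiclonal"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not (0 < self.mm_depth < self.depth):
            raise ValueError("need 0 < mm_depth < depth")
        for p in (self.mixing_prob, self.invasion_prob, self.driver_prob):
            if not (0 <= p <= 1):
                raise ValueError("probabilities must lie in [0, 1]")
        if not (0 < self.cellularity <= 1):
            raise ValueError("cellularity must lie in (0, 1]")
        if self.n_public > self.panel_size:
            raise ValueError("n_public exceeds panel_size")


@dataclass
class Gland:
    gland_id: int
    pos: tuple[int, int]                 # (column, row); row >= mm_depth is invasive
    parent: int | None
    mutations: frozenset                 # panel locus indices
    n_private_drivers: int
    invasion_event: int | None           # founding event id if below the MM


@dataclass
class InvasionEvent:
    event_id: int
    gland_id: int                        # first gland below the MM for this lineage
    division_index: int
    parent_gland: int


@dataclass
class SimTruth:
    """Ground-truth lineage, migration events and spot compositions."""

    config: SimConfig
    glands: list[Gland]
    events: list[InvasionEvent]
    spot_composition: dict[str, list[int]] = field(default_factory=dict)
    met_genotype: frozenset | None = None
    n_divisions: int = 0

    def gland(self, gland_id: int) -> Gland:
        return self.glands[gland_id]

    def sampled_gland_ids(self) -> list[int]:
        out: set[int] = set()
        for ids in self.spot_composition.values():
            out.update(ids)
        return sorted(out)

    def detectable_genotypes(self) -> dict[str, frozenset]:
        """Per-spot genotype over loci that reach at least one spot.

        Meaningful for clonal spots; a multi-gland spot gets the
        intersection-free union of its gland genotypes restricted to the
        sampled loci (for single-gland spots this is exact).
        """
        sampled_loci: set[int] = set()
        for ids in self.spot_composition.values():
            for g in ids:
                sampled_loci |= self.glands[g].mutations
        out = {}
        for sid, ids in self.spot_composition.items():
            union: set[int] = set()
            for g in ids:
                union |= self.glands[g].mutations
            out[sid] = frozenset(union & sampled_loci)
        return out

    def n_founding_lineages(self, spot_ids=None) -> int:
        """Distinct true invasion events ancestral to sampled invaded glands."""
        ids = self.spot_composition if spot_ids is None else spot_ids
        events = set()
        for sid in ids:
            for g in self.spot_composition[sid]:
                ev = self.glands[g].invasion_event
                if ev is not None:
                    events.add(ev)
        return len(events)

    def to_json(self, path: str | Path) -> None:
        doc = {
            "config": asdict(self.config),
            "n_divisions": self.n_divisions,
            "glands": [
                {
                    "gland_id": g.gland_id, "pos": list(g.pos), "parent": g.parent,
                    "mutations": sorted(g.mutations),
                    "n_private_drivers": g.n_private_drivers,
                    "invasion_event": g.invasion_event,
                }
                for g in self.glands
            ],
            "events": [asdict(e) for e in self.events],
            "spot_composition": self.spot_composition,
            "met_genotype": sorted(self.met_genotype) if self.met_genotype is not None else None,
        }
        Path(path).write_text(json.dumps(doc, indent=2) + "\n")


@dataclass
class SimOutput:
    vafs: VAFMatrix
    truth: SimTruth | None
    expected: dict | None = None


# ---------------------------------------------------------------------------
# Growth
# ---------------------------------------------------------------------------

_NEIGH4 = ((1, 0), (-1, 0), (0, 1), (0, -1))


def _grow(cfg: SimConfig, rng: np.random.Generator) -> SimTruth:
    width, depth, mm = cfg.width, cfg.depth, cfg.mm_depth
    founder_pos = (width // 2, max(0, mm - 3))
    founder = Gland(0, founder_pos, None, frozenset(range(cfg.n_public)), 0, None)
    glands = [founder]
    occupied: dict[tuple[int, int], int] = {founder_pos: 0}
    unused = list(range(cfg.n_public, cfg.panel_size))
    events: list[InvasionEvent] = []
    divisions = 0
    met_genotype: frozenset | None = None
    attempts = 0
    max_attempts = 200 * cfg.target_glands

    def in_bounds(p: tuple[int, int]) -> bool:
        return 0 <= p[0] < width and 0 <= p[1] < depth

    while len(glands) < cfg.target_glands and attempts < max_attempts:
        attempts += 1
        parent = glands[rng.integers(0, len(glands))]
        px, py = parent.pos
        if rng.random() < cfg.mixing_prob:
            r = cfg.mixing_radius
            sites = [
                (px + dx, py + dy)
                for dx in range(-r, r + 1) for dy in range(-r, r + 1)
                if (dx, dy) != (0, 0)
            ]
        else:
            sites = [(px + dx, py + dy) for dx, dy in _NEIGH4]
        sites = [p for p in sites if in_bounds(p) and p not in occupied]
        if not sites:
            continue
        target = sites[rng.integers(0, len(sites))]
        parent_below = py >= mm
        target_below = target[1] >= mm
        crossing = (not parent_below) and target_below
        if parent_below and not target_below:
            continue  # irreversible: no migration back above the MM
        if crossing:
            if cfg.mode == "bottleneck":
                if parent.n_private_drivers < cfg.n_drivers_required:
                    continue
            else:
                if rng.random() >= cfg.invasion_prob:
                    continue

        k = int(rng.poisson(cfg.mutation_rate))
        if k > len(unused):
            raise ValueError(
                f"panel exhausted after {len(glands)} glands; "
                "increase panel_size or lower mutation_rate"
            )
        new_loci: list[int] = []
        for _ in range(k):
            j = unused.pop(int(rng.integers(0, len(unused))))
            new_loci.append(j)
        n_new_drivers = int(sum(rng.random() < cfg.driver_prob for _ in new_loci))

        gid = len(glands)
        if crossing:
            event = InvasionEvent(len(events), gid, divisions, parent.gland_id)
            events.append(event)
            ev_id = event.event_id
        elif parent_below:
            ev_id = parent.invasion_event
        else:
            ev_id = None
        child = Gland(
            gid, target, parent.gland_id,
            parent.mutations | frozenset(new_loci),
            parent.n_private_drivers + n_new_drivers,
            ev_id,
        )
        glands.append(child)
        occupied[target] = gid
        divisions += 1

        if (
            cfg.met_divergence_time is not None
            and met_genotype is None
            and divisions >= cfg.met_divergence_time * cfg.target_glands
        ):
            above = [g for g in glands if g.pos[1] < mm]
            donor = above[rng.integers(0, len(above))] if above else glands[-1]
            met_genotype = donor.mutations

    if cfg.met_divergence_time is not None and met_genotype is None:
        met_genotype = glands[0].mutations
    return SimTruth(cfg, glands, events, {}, met_genotype, divisions)


# ---------------------------------------------------------------------------
# Sampling and sequencing
# ---------------------------------------------------------------------------

def sample_spots(truth: SimTruth, cfg: SimConfig, rng: np.random.Generator) -> dict[str, list[int]]:
    """Choose spot centers with minimum separation; spots are the center
    gland plus its nearest occupied neighbors up to ``glands_per_spot``."""
    positions = sorted(g.pos for g in truth.glands)
    pos_to_gland = {g.pos: g.gland_id for g in truth.glands}
    order = rng.permutation(len(positions))
    centers: list[tuple[int, int]] = []
    for i in order:
        p = positions[i]
        if all(math.dist(p, c) >= cfg.min_spot_separation for c in centers):
            centers.append(p)
        if len(centers) == cfg.n_spots:
            break
    if len(centers) < cfg.n_spots:
        raise ValueError(
            f"cannot place {cfg.n_spots} spots at separation "
            f"{cfg.min_spot_separation} in a {len(positions)}-gland tumor"
        )
    composition: dict[str, list[int]] = {}
    for k, center in enumerate(sorted(centers)):
        near = sorted(positions, key=lambda p: (math.dist(p, center), p))
        members = [pos_to_gland[p] for p in near[: cfg.glands_per_spot]]
        composition[f"s{k + 1:02d}"] = members
    return composition


def emit_vaf_reads(
    gland_mutation_sets: list[frozenset],
    cfg: SimConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Sequence one spot: per-locus VAF and depth rows.

    The true alt fraction is carrier-fraction x 0.5 x cellularity
    (heterozygous somatic mutations), with an error floor for absent
    loci; reads are Poisson-depth / binomial-alt unless ``noise_free``.
    """
    n_glands = len(gland_mutation_sets)
    vaf = np.zeros(cfg.panel_size)
    depth = np.zeros(cfg.panel_size, dtype=np.int64)
    for j in range(cfg.panel_size):
        carrying = sum(1 for m in gland_mutation_sets if j in m)
        f = (carrying / n_glands) * 0.5 * cfg.cellularity
        p = f if f > 0 else ERROR_FLOOR
        if cfg.noise_free:
            d = int(cfg.depth_mean)
            a = int(round(p * d))
        else:
            d = int(rng.poisson(cfg.depth_mean))
            a = int(rng.binomial(d, p)) if d > 0 else 0
        depth[j] = d
        vaf[j] = a / d if d > 0 else np.nan
    return vaf, depth


def _panel_loci(cfg: SimConfig) -> list[Locus]:
    loci = []
    for j in range(cfg.panel_size):
        is_driver = j < 2 and cfg.n_public >= 2  # founder drivers (e.g. TP53/APC-like)
        loci.append(Locus(f"L{j + 1:02d}", is_driver=is_driver))
    return loci


def simulate_tumor(cfg: SimConfig) -> SimOutput:
    """Grow, sample and sequence one synthetic tumor section."""
    rng = np.random.default_rng(cfg.rng_seed)
    truth = _grow(cfg, rng)
    truth.spot_composition = sample_spots(truth, cfg, rng)

    loci = _panel_loci(cfg)
    spot_rows = []
    vaf_rows, depth_rows = [], []
    for sid, gland_ids in truth.spot_composition.items():
        muts = [truth.glands[g].mutations for g in gland_ids]
        v, d = emit_vaf_reads(muts, cfg, rng)
        center = truth.glands[gland_ids[0]].pos
        pheno = "S" if center[1] < cfg.mm_depth else "I"
        spot_rows.append(
            SpotRecord(
                spot_id=sid, tumor_id="SIM", slide_id="X",
                x_mm=center[0] * cfg.lattice_mm, y_mm=center[1] * cfg.lattice_mm,
                phenotype=pheno, site="primary",
            )
        )
        vaf_rows.append(v)
        depth_rows.append(d)

    if truth.met_genotype is not None:
        n_met = int(rng.integers(1, 3))
        for k in range(n_met):
            v, d = emit_vaf_reads([truth.met_genotype], cfg, rng)
            sid = f"met{k + 1}"
            spot_rows.append(
                SpotRecord(
                    spot_id=sid, tumor_id="SIM", slide_id="LN",
                    phenotype="M", site="lymph_node",
                )
            )
            vaf_rows.append(v)
            depth_rows.append(d)
            truth.spot_composition[sid] = []

    vafs = VAFMatrix(spot_rows, loci, np.array(vaf_rows), np.array(depth_rows))
    return SimOutput(vafs, truth)


# ---------------------------------------------------------------------------
# Deterministic worked fixture
# ---------------------------------------------------------------------------

def make_worked_fixture() -> SimOutput:
    """A tiny handcrafted tumor used throughout the tests and docs.

    Five subclones over a 20-locus panel (5 public mutations, two of
    them canonical drivers): two mixed S-I clones (A, B, sisters), one
    purely superficial pair (D, E), and an invasive clone C that carries
    exactly the public genotype and is shared with a lymph-node
    metastasis — so the minimal invasion history has 3 events (one per
    S-I clone plus one for the invasive/metastatic clade).  One spot is
    a deliberate 40:60 admixture of clones A and D, which creates
    four-gamete violations and a diluted private-VAF spectrum.
    """
    loci = [
        Locus("L01", gene_label="TP53", is_driver=True),
        Locus("L02", gene_label="APC", is_driver=True),
    ] + [Locus(f"L{j:02d}") for j in range(3, 21)]
    idx = {l.locus_id: j for j, l in enumerate(loci)}

    publics = ["L01", "L02", "L03", "L04", "L05"]
    geno = {
        "A": publics + ["L06", "L07", "L08", "L09"],
        "B": publics + ["L06", "L07", "L10", "L11", "L12"],
        "C": list(publics),
        "D": publics + ["L13", "L14"],
        "E": publics + ["L15", "L16", "L17", "L18", "L19", "L20"],
    }
    frac = {name: {idx[l]: 1.0 for l in ls} for name, ls in geno.items()}

    # spot_id, composition {clone: fraction}, slide, x, y, phenotype, site
    spots = [
        ("a1", {"A": 1.0}, "X", 2.0, 3.0, "S", "primary"),
        ("a2", {"A": 1.0}, "X", 2.0, 6.0, "I", "primary"),
        ("a3", {"A": 1.0}, "X", 3.0, 6.0, "I", "primary"),
        ("b1", {"B": 1.0}, "X", 5.0, 3.0, "S", "primary"),
        ("b2", {"B": 1.0}, "X", 6.0, 3.0, "S", "primary"),
        ("b3", {"B": 1.0}, "Y", 5.0, 6.0, "I", "primary"),
        ("c1", {"C": 1.0}, "X", 8.0, 6.0, "I", "primary"),
        ("c2", {"C": 1.0}, "Y", 8.0, 6.0, "I", "primary"),
        ("d1", {"D": 1.0}, "X", 11.0, 3.0, "S", "primary"),
        ("d2", {"D": 1.0}, "Y", 11.0, 3.0, "S", "primary"),
        ("e1", {"E": 1.0}, "X", 14.0, 3.0, "S", "primary"),
        ("e2", {"E": 1.0}, "Y", 14.0, 3.0, "S", "primary"),
        ("adm1", {"A": 0.4, "D": 0.6}, "X", 4.0, 4.0, "S", "primary"),
        ("met1", {"C": 1.0}, "LN", math.nan, math.nan, "M", "lymph_node"),
    ]

    rng = np.random.default_rng(20)
    cellularity = 1.0
    records, vaf_rows, depth_rows = [], [], []
    for sid, mix, slide, x, y, pheno, site in spots:
        records.append(
            SpotRecord(spot_id=sid, tumor_id="WF", slide_id=slide,
                       x_mm=x, y_mm=y, phenotype=pheno, site=site)
        )
        v = np.zeros(len(loci))
        d = np.zeros(len(loci), dtype=np.int64)
        for j in range(len(loci)):
            f = sum(w * frac[c].get(j, 0.0) for c, w in mix.items()) * 0.5 * cellularity
            p = f if f > 0 else ERROR_FLOOR
            dd = int(rng.poisson(9000))
            aa = int(rng.binomial(dd, p))
            d[j] = dd
            v[j] = aa / dd
        vaf_rows.append(v)
        depth_rows.append(d)

    vafs = VAFMatrix(records, loci, np.array(vaf_rows), np.array(depth_rows))
    expected = {
        "n_subclones": 5,
        "n_events": 3,
        "admixed_spots": ["adm1"],
        "monophyletic": False,
        "clone_genotypes": {name: sorted(ls) for name, ls in geno.items()},
        "met_matches_public_set": True,
        "early_invasion": True,
    }
    return SimOutput(vafs, truth=None, expected=expected)
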