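"""From VAFs to clean binary spot genotypes and subclones.

Processing chain (deterministic, idempotent):

    call -> singleton-noise removal -> admixed-spot removal ->
    public promotion -> scope classification -> homoplasy resolution ->
    subclone collapse

Spots are assumed clonal (2-5 glands), so a heterozygous somatic
mutation sits near VAF = 0.5 x cellularity and a simple threshold call
is adequate.  The homoplasy-resolution step enforces the infinite-sites
assumption (each mutation acquired once, never reverted), i.e. the
four-gamete condition on every locus pair, by flipping the minimum
number of calls.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .datamodel import Locus, PipelineConfig, SpotRecord, VAFMatrix

# call codes
PRESENT, ABSENT, MISSING = 1, 0, -1
# provenance codes
OBSERVED, SINGLETON_NOISE_REMOVED, FALSE_NEGATIVE_PROMOTED, HOMOPLASY_FLIP = 0, 1, 2, 3

PROVENANCE_NAMES = {
    OBSERVED: "observed",
    SINGLETON_NOISE_REMOVED: "singleton_noise_removed",
    FALSE_NEGATIVE_PROMOTED: "false_negative_promoted",
    HOMOPLASY_FLIP: "homoplasy_flip",
}

__all__ = [
    "CallMatrix",
    "Subclone",
    "AdmixtureFlag",
    "PreprocessResult",
    "call_mutations",
    "remove_singleton_noise",
    "promote_public",
    "classify_scope",
    "detect_admixed_spots",
    "resolve_homoplasy",
    "collapse_subclones",
    "preprocess",
    "violating_pairs",
    "min_flips_exhaustive",
]


@dataclass
class CallMatrix:
    """Ternary call matrix with per-cell provenance.

    ``calls`` holds 1 (present), 0 (absent) or -1 (missing, depth below
    the minimum); ``provenance`` records which preprocessing rule last
    touched each cell.
    """

    spots: list[SpotRecord]
    loci: list[Locus]
    calls: np.ndarray       # int8, spots x loci
    provenance: np.ndarray  # int8, spots x loci
    public_loci: set[str] = field(default_factory=set)
    dropped_loci: set[str] = field(default_factory=set)
    excluded_spots: dict[str, str] = field(default_factory=dict)  # spot_id -> reason
    audit: list[dict] = field(default_factory=list)

    # -- helpers -----------------------------------------------------------
    @property
    def spot_ids(self) -> list[str]:
        return [s.spot_id for s in self.spots]

    @property
    def locus_ids(self) -> list[str]:
        return [l.locus_id for l in self.loci]

    def included_indices(self) -> list[int]:
        return [i for i, s in enumerate(self.spots) if s.spot_id not in self.excluded_spots]

    def copy(self) -> "CallMatrix":
        return CallMatrix(
            list(self.spots), list(self.loci), self.calls.copy(), self.provenance.copy(),
            set(self.public_loci), set(self.dropped_loci), dict(self.excluded_spots),
            list(self.audit),
        )

    def effective_binary(self) -> tuple[np.ndarray, list[int]]:
        """Binary genotype matrix over included spots.

        Missing cells resolve to present for public (promoted) loci and
        to absent otherwise; some convention is required because each
        spot is assigned a complete genotype.
        """
        idx = self.included_indices()
        sub = self.calls[idx, :].copy()
        for j, locus in enumerate(self.loci):
            fill = PRESENT if locus.locus_id in self.public_loci else ABSENT
            sub[:, j] = np.where(sub[:, j] == MISSING, fill, sub[:, j])
        return sub.astype(np.int8), idx

    def log(self, rule: str, **detail) -> None:
        self.audit.append({"rule": rule, **detail})


@dataclass(frozen=True)
class Subclone:
    """A set of spots sharing one binary genotype."""

    subclone_id: str
    genotype: tuple[int, ...]      # over the panel loci, in CallMatrix order
    member_spots: tuple[SpotRecord, ...]
    n_private_mutations: int       # mutations carried by this subclone alone

    @property
    def mutations(self) -> frozenset:
        return frozenset(i for i, g in enumerate(self.genotype) if g)


@dataclass(frozen=True)
class AdmixtureFlag:
    spot_id: str
    reason: str                    # low_private_vaf | homoplasy | both
    private_vaf_ratio: float


@dataclass
class PreprocessResult:
    call_matrix: CallMatrix
    subclones: list[Subclone]
    admixture_flags: list[AdmixtureFlag]
    n_homoplasy_flips: int


# ---------------------------------------------------------------------------
# Calling and noise rules
# ---------------------------------------------------------------------------

def call_mutations(vafs: VAFMatrix, cfg: PipelineConfig) -> CallMatrix:
    """Threshold VAFs into present/absent/missing calls.

    present iff depth >= min_depth and vaf >= vaf_call_threshold;
    absent iff depth >= min_depth and vaf < threshold; missing otherwise.
    Spots with too many missing loci are excluded with a warning.
    """
    n_s, n_l = vafs.shape
    calls = np.full((n_s, n_l), MISSING, dtype=np.int8)
    ok = vafs.depth >= cfg.min_depth
    with np.errstate(invalid="ignore"):
        calls[ok & (vafs.vaf >= cfg.vaf_call_threshold)] = PRESENT
        calls[ok & (vafs.vaf < cfg.vaf_call_threshold)] = ABSENT
    cm = CallMatrix(
        spots=list(vafs.spots),
        loci=list(vafs.loci),
        calls=calls,
        provenance=np.full((n_s, n_l), OBSERVED, dtype=np.int8),
    )
    missing_frac = (calls == MISSING).mean(axis=1)
    for i, s in enumerate(cm.spots):
        if missing_frac[i] > cfg.max_missing_fraction:
            cm.excluded_spots[s.spot_id] = "high_missing"
            cm.log("exclude_high_missing", spot_id=s.spot_id,
                   missing_fraction=float(missing_frac[i]))
            warnings.warn(
                f"spot {s.spot_id}: {missing_frac[i]:.0%} loci below min depth; excluded",
                stacklevel=2,
            )
    return cm


def remove_singleton_noise(cm: CallMatrix, vafs: VAFMatrix, cfg: PipelineConfig) -> CallMatrix:
    """Reclassify low-VAF single-spot private mutations as absent.

    A mutation present in exactly one spot with VAF below the
    singleton-noise cutoff is interpreted as sequencing noise.
    """
    out = cm.copy()
    idx = out.included_indices()
    for j, locus in enumerate(out.loci):
        carriers = [i for i in idx if out.calls[i, j] == PRESENT]
        if len(carriers) != 1:
            continue
        i = carriers[0]
        if vafs.vaf[i, j] < cfg.singleton_noise_vaf:
            out.calls[i, j] = ABSENT
            out.provenance[i, j] = SINGLETON_NOISE_REMOVED
            out.log("singleton_noise_removed", spot_id=out.spots[i].spot_id,
                    locus_id=locus.locus_id, vaf=float(vafs.vaf[i, j]))
    return out


def promote_public(cm: CallMatrix, cfg: PipelineConfig) -> CallMatrix:
    """Promote near-ubiquitous mutations to public.

    A mutation present in strictly more than ``public_promotion_fraction``
    of the callable (non-missing, non-excluded) spots is deemed public;
    its absences are false negatives and flip to present.
    """
    out = cm.copy()
    idx = out.included_indices()
    for j, locus in enumerate(out.loci):
        col = out.calls[idx, j]
        callable_n = int((col != MISSING).sum())
        if callable_n == 0:
            continue
        n_present = int((col == PRESENT).sum())
        if n_present == callable_n:
            out.public_loci.add(locus.locus_id)
            continue
        if n_present > cfg.public_promotion_fraction * callable_n:
            out.public_loci.add(locus.locus_id)
            for i in idx:
                if out.calls[i, j] == ABSENT:
                    out.calls[i, j] = PRESENT
                    out.provenance[i, j] = FALSE_NEGATIVE_PROMOTED
                    out.log("false_negative_promoted", spot_id=out.spots[i].spot_id,
                            locus_id=locus.locus_id)
    return out


def classify_scope(cm: CallMatrix) -> dict[str, str]:
    """Classify each locus as public (all spots) or private (strict subset).

    Loci absent everywhere are dropped with a warning and omitted from
    the returned mapping.
    """
    binary, _ = cm.effective_binary()
    scope: dict[str, str] = {}
    for j, locus in enumerate(cm.loci):
        n_present = int(binary[:, j].sum())
        if n_present == 0:
            if locus.locus_id not in cm.dropped_loci:
                cm.dropped_loci.add(locus.locus_id)
                cm.log("locus_dropped_absent_everywhere", locus_id=locus.locus_id)
                warnings.warn(f"locus {locus.locus_id} absent in all spots; dropped",
                              stacklevel=2)
            continue
        scope[locus.locus_id] = "public" if n_present == binary.shape[0] else "private"
    return scope


# ---------------------------------------------------------------------------
# Four-gamete machinery (shared with the phylogeny module)
# ---------------------------------------------------------------------------

def violating_pairs(binary: np.ndarray) -> list[tuple[int, int]]:
    """Column pairs failing the four-gamete test.

    The germline all-absent genotype is implicitly present, so a pair is
    incompatible iff the patterns 01, 10 and 11 all occur among rows.
    """
    b = np.asarray(binary, dtype=bool)
    n_l = b.shape[1]
    out = []
    for p in range(n_l):
        cp = b[:, p]
        for q in range(p + 1, n_l):
            cq = b[:, q]
            has_11 = bool(np.any(cp & cq))
            has_10 = bool(np.any(cp & ~cq))
            has_01 = bool(np.any(~cp & cq))
            if has_11 and has_10 and has_01:
                out.append((p, q))
    return out


def _pair_violates(b: np.ndarray, p: int, q: int) -> bool:
    cp, cq = b[:, p].astype(bool), b[:, q].astype(bool)
    return bool(np.any(cp & cq) and np.any(cp & ~cq) and np.any(~cp & cq))


def min_flips_exhaustive(binary: np.ndarray, max_flips: int = 4) -> int:
    """Brute-force minimum number of cell flips to reach compatibility.

    Independent oracle for :func:`resolve_homoplasy`; exponential, use
    only on tiny matrices.
    """
    from itertools import combinations

    b = np.asarray(binary, dtype=np.int8)
    cells = [(r, c) for r in range(b.shape[0]) for c in range(b.shape[1])]
    for k in range(max_flips + 1):
        for combo in combinations(cells, k):
            trial = b.copy()
            for r, c in combo:
                trial[r, c] ^= 1
            if not violating_pairs(trial):
                return k
    raise ValueError(f"no solution within {max_flips} flips")


# ---------------------------------------------------------------------------
# Admixture detection
# ---------------------------------------------------------------------------

def _provisional_scope(cm: CallMatrix, cfg: PipelineConfig) -> dict[str, str]:
    # Promotion has not yet run when admixture is assessed, so use the
    # promotion fraction itself to decide what will count as public.
    idx = cm.included_indices()
    scope = {}
    for j, locus in enumerate(cm.loci):
        col = cm.calls[idx, j]
        callable_n = int((col != MISSING).sum())
        n_present = int((col == PRESENT).sum())
        if n_present == 0 or callable_n == 0:
            continue
        frac = n_present / callable_n
        scope[locus.locus_id] = "public" if frac > cfg.public_promotion_fraction else "private"
    return scope


def detect_admixed_spots(
    cm: CallMatrix, vafs: VAFMatrix, cfg: PipelineConfig
) -> list[AdmixtureFlag]:
    """Flag spots whose VAF spectrum indicates a mixture of subclones.

    A spot is flagged when both hold: (a) it is pivotal for at least one
    four-gamete violation (removing it makes that locus pair compatible),
    and (b) its median private-mutation VAF is below half its median
    public-mutation VAF — in a clonal spot private and public VAFs are
    comparable, while in a mixture the privates of each component are
    diluted.
    """
    scope = _provisional_scope(cm, cfg)
    idx = cm.included_indices()
    binary = (cm.calls[idx, :] == PRESENT).astype(np.int8)
    viol = violating_pairs(binary)
    flags: list[AdmixtureFlag] = []
    for row, i in enumerate(idx):
        spot = cm.spots[i]
        pivotal = False
        for (p, q) in viol:
            pat = (binary[row, p], binary[row, q])
            if pat == (0, 0):
                continue
            rest = np.delete(binary, row, axis=0)
            if not _pair_violates(rest, p, q):
                pivotal = True
                break
        if not pivotal:
            continue
        pub_vafs = [
            vafs.vaf[i, j] for j, l in enumerate(cm.loci)
            if scope.get(l.locus_id) == "public" and cm.calls[i, j] == PRESENT
        ]
        prv_vafs = [
            vafs.vaf[i, j] for j, l in enumerate(cm.loci)
            if scope.get(l.locus_id) == "private" and cm.calls[i, j] == PRESENT
        ]
        if not pub_vafs or not prv_vafs:
            continue
        ratio = float(np.median(prv_vafs) / np.median(pub_vafs))
        if ratio < 0.5:
            flags.append(AdmixtureFlag(spot.spot_id, "both", ratio))
    return flags


def exclude_spots(cm: CallMatrix, flags: list[AdmixtureFlag]) -> CallMatrix:
    out = cm.copy()
    for fl in flags:
        out.excluded_spots[fl.spot_id] = "admixed"
        out.log("exclude_admixed", spot_id=fl.spot_id,
                private_vaf_ratio=fl.private_vaf_ratio, reason=fl.reason)
    return out


# ---------------------------------------------------------------------------
# Homoplasy resolution (minimum-flip branch and bound)
# ---------------------------------------------------------------------------

def resolve_homoplasy(
    cm: CallMatrix, vafs: VAFMatrix | None = None, cfg: PipelineConfig | None = None
) -> CallMatrix:
    """Flip the minimum number of calls to satisfy the four-gamete test.

    Exact search by iterative-deepening branch and bound over cells in
    violating column pairs.  Ties are broken by preferring
    present-to-absent flips at the lowest-VAF cell (weak calls are the
    likelier false positives).  Raises if the minimal flip count exceeds
    the configured budget.
    """
    cfg = cfg or PipelineConfig()
    out = cm.copy()
    binary, idx = out.effective_binary()
    n_cells = binary.size
    budget = max(1, math.ceil(cfg.homoplasy_flip_budget * n_cells))

    def vaf_of(row: int, col: int) -> float:
        if vafs is None:
            return 0.5
        v = vafs.vaf[idx[row], col]
        return 0.5 if math.isnan(v) else float(v)

    def candidates(b: np.ndarray, p: int, q: int) -> list[tuple[int, int]]:
        cells = []
        for r in range(b.shape[0]):
            if (b[r, p], b[r, q]) == (0, 0):
                continue
            cells.extend([(r, p), (r, q)])
        # tie rule: present->absent first, ascending VAF; then absent->present
        cells.sort(key=lambda rc: (
            0 if b[rc[0], rc[1]] == 1 else 1,
            vaf_of(*rc) if b[rc[0], rc[1]] == 1 else -vaf_of(*rc),
            rc,
        ))
        return cells

    def search(b: np.ndarray, depth: int, flipped: frozenset) -> list[tuple[int, int]] | None:
        viol = violating_pairs(b)
        if not viol:
            return []
        if depth == 0 or len(viol) > depth * b.shape[0]:
            # each flip affects one row; a pair needs >= 1 flip, coarse prune
            if depth == 0:
                return None
        p, q = viol[0]
        for rc in candidates(b, p, q):
            if rc in flipped:
                continue
            b2 = b.copy()
            b2[rc] ^= 1
            rest = search(b2, depth - 1, flipped | {rc})
            if rest is not None:
                return [rc] + rest
        return None

    solution = None
    for d in range(budget + 1):
        solution = search(binary, d, frozenset())
        if solution is not None:
            break
    if solution is None:
        raise ValueError(
            f"homoplasy resolution needs more than {budget} flips "
            f"({cfg.homoplasy_flip_budget:.0%} of cells); manual review advised"
        )
    for r, c in solution:
        i = idx[r]
        binary[r, c] ^= 1
        out.calls[i, c] = PRESENT if binary[r, c] else ABSENT
        out.provenance[i, c] = HOMOPLASY_FLIP
        out.log("homoplasy_flip", spot_id=out.spots[i].spot_id,
                locus_id=out.loci[c].locus_id,
                new_call="present" if binary[r, c] else "absent")
    out.log("homoplasy_summary", n_flips=len(solution))
    return out


# ---------------------------------------------------------------------------
# Subclone collapse
# ---------------------------------------------------------------------------

def collapse_subclones(cm: CallMatrix, spots: list[SpotRecord] | None = None) -> list[Subclone]:
    """Group spots by identical genotype; unique genotypes are subclones.

    Dropped (absent-everywhere) loci are zeroed so they never split
    genotypes.  Subclones are ordered by descending size then first
    member, and labelled SC1, SC2, ...
    """
    binary, idx = cm.effective_binary()
    dropped_cols = [j for j, l in enumerate(cm.loci) if l.locus_id in cm.dropped_loci]
    if dropped_cols:
        binary = binary.copy()
        binary[:, dropped_cols] = 0
    groups: dict[tuple, list[int]] = {}
    for row, i in enumerate(idx):
        key = tuple(int(x) for x in binary[row, :])
        groups.setdefault(key, []).append(i)
    ordered = sorted(groups.items(), key=lambda kv: (-len(kv[1]), min(kv[1])))
    # private-to-subclone mutation counts
    subclones = []
    for rank, (geno, members) in enumerate(ordered, start=1):
        others = np.zeros(len(cm.loci), dtype=bool)
        for g2, _m in ordered:
            if g2 != geno:
                others |= np.asarray(g2, dtype=bool)
        n_priv = int(np.sum(np.asarray(geno, dtype=bool) & ~others))
        subclones.append(
            Subclone(
                subclone_id=f"SC{rank}",
                genotype=geno,
                member_spots=tuple(cm.spots[i] for i in members),
                n_private_mutations=n_priv,
            )
        )
    return subclones


# ---------------------------------------------------------------------------
# Full chain
# ---------------------------------------------------------------------------

def preprocess(vafs: VAFMatrix, cfg: PipelineConfig | None = None) -> PreprocessResult:
    """Run the complete genotyping chain on a VAF matrix."""
    cfg = cfg or PipelineConfig()
    cm = call_mutations(vafs, cfg)
    cm = remove_singleton_noise(cm, vafs, cfg)
    flags = detect_admixed_spots(cm, vafs, cfg)
    cm = exclude_spots(cm, flags)
    cm = promote_public(cm, cfg)
    classify_scope(cm)
    cm = resolve_homoplasy(cm, vafs, cfg)
    subclones = collapse_subclones(cm)
    n_flips = sum(1 for e in cm.audit if e["rule"] == "homoplasy_flip")
    return PreprocessResult(cm, subclones, flags, n_flips)
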