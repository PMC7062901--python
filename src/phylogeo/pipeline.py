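"""End-to-end orchestration, study-level census, and the command line.

``run_pipeline`` executes the full chain per tumor — calling, noise
removal, admixture exclusion, public promotion, homoplasy resolution,
subclone collapse, perfect-phylogeny reconstruction, bootstrap,
phenotype merging, invasion-event counting, timing, and the summary
statistics — and returns a JSON-serializable report.
``summarize_study`` computes the study-wide marginals from per-tumor
census rows.
"""

from __future__ import annotations

import json
import logging
import statistics as pystats
from dataclasses import asdict
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import click
import numpy as np

from .clonestats import (
    SubcloneCensus,
    contiguity_fraction,
    gini_simpson,
    ks_uniform,
    normalized_adjacency_distance,
    spatial_genetic_correlation,
    within_between_slide_distances,
)
from .datamodel import (
    CloneTree,
    PipelineConfig,
    StudySummaryRow,
    VAFMatrix,
    load_study_summary,
    newick_string,
    read_vaf_table,
    write_newick,
    write_vaf_table,
)
from .genotyping import PreprocessResult, Subclone, classify_scope, preprocess
from .phylogeny import bootstrap_support, build_perfect_phylogeny
from .phylogeography import (
    assign_subclone_phenotypes,
    compare_metastasis_genotype,
    count_invasion_events,
)
from .simulate import SimConfig, simulate_tumor

log = logging.getLogger("phylogeo")

__all__ = ["run_pipeline", "analyze_tumor", "summarize_study", "report_to_summary_row",
           "validate_report", "cli"]


def _phenotype_eligible(subclones: Sequence[Subclone]) -> list[Subclone]:
    """Drop unlabeled primary spots from membership (they are excluded
    from phylogeography but keep their genotyping role)."""
    out = []
    for sc in subclones:
        members = tuple(
            s for s in sc.member_spots if not s.is_primary or s.phenotype is not None
        )
        out.append(Subclone(sc.subclone_id, sc.genotype, members, sc.n_private_mutations))
    return out


def _primary_scope(subclones: Sequence[Subclone], locus_ids: Sequence[str]) -> dict[str, str]:
    """Public/private scope over primary-tumor subclones only (the
    reference frame for metastasis divergence)."""
    primary = [sc for sc in subclones if any(s.is_primary for s in sc.member_spots)]
    scope = {}
    for j, lid in enumerate(locus_ids):
        carried = [bool(sc.genotype[j]) for sc in primary]
        if not any(carried):
            continue
        scope[lid] = "public" if all(carried) else "private"
    return scope


def analyze_tumor(vafs: VAFMatrix, cfg: PipelineConfig | None = None) -> dict:
    """Run the full pipeline on one tumor's VAF matrix."""
    cfg = cfg or PipelineConfig()
    tumor_ids = {s.tumor_id for s in vafs.spots}
    if len(tumor_ids) != 1:
        raise ValueError(f"expected a single tumor, got {sorted(tumor_ids)}")
    tumor_id = tumor_ids.pop()
    log.info("tumor %s: %d spots x %d loci", tumor_id, *vafs.shape)

    prep: PreprocessResult = preprocess(vafs, cfg)
    cm = prep.call_matrix
    scope = classify_scope(cm)
    subclones = _phenotype_eligible(prep.subclones)
    locus_ids = cm.locus_ids

    tree = build_perfect_phylogeny(prep.subclones, locus_ids)
    boot = bootstrap_support(prep.subclones, cfg, tree=tree, locus_ids=locus_ids)
    phenotypes = assign_subclone_phenotypes(subclones)
    invasion = count_invasion_events(tree, phenotypes, cfg, tumor_id=tumor_id)

    # metastasis divergence (if metastatic samples exist)
    met_block = None
    met_subs = [sc for sc in subclones if any(not s.is_primary for s in sc.member_spots)]
    if met_subs:
        pscope = _primary_scope(subclones, locus_ids)
        div = compare_metastasis_genotype(met_subs,
                                          [sc for sc in subclones
                                           if any(s.is_primary for s in sc.member_spots)],
                                          pscope, loci=cm.loci)
        met_block = {
            "met_subclones": [sc.subclone_id for sc in met_subs],
            "identical_across_met": div.identical_across_met,
            "private_carried": div.private_carried,
            "public_missing": div.public_missing,
            "drivers_missing": div.drivers_missing,
            "early_divergence": div.early_divergence,
        }

    stats_block = _statistics_block(vafs, cm, subclones, tree, cfg)
    newick = newick_string(tree, support=boot.support)
    pheno_by_id = {ph.subclone_id: ph for ph in phenotypes}

    report = {
        "tumor_id": tumor_id,
        "n_spots_total": len(vafs.spots),
        "n_spots_used": len(cm.included_indices()),
        "n_loci": len(locus_ids),
        "n_subclones": len(subclones),
        "subclones": [
            {
                "subclone_id": sc.subclone_id,
                "n_spots": len(sc.member_spots),
                "n_private_mutations": sc.n_private_mutations,
                "mutations": [locus_ids[j] for j in sorted(sc.mutations)],
                "member_spots": [s.spot_id for s in sc.member_spots],
                "phenotype_class": pheno_by_id[sc.subclone_id].pclass,
                "has_metastatic_member": pheno_by_id[sc.subclone_id].has_metastatic_member,
            }
            for sc in subclones
        ],
        "scope": scope,
        "newick": newick,
        "bootstrap": {
            "n_replicates": boot.n_replicates,
            "supports": {
                "|".join(sorted(tree.clade_tips(v))): s
                for (u, v), s in boot.support.items()
            },
        },
        "invasion": {
            "invading_subclones": invasion.invading_subclones,
            "monophyletic": invasion.monophyletic,
            "multiclonal": invasion.n_events >= 2,
            "n_events": invasion.n_events,
            "early_invasion": invasion.early_invasion,
            "per_event": invasion.per_event,
            "timing": [asdict(t) for t in invasion.timing],
        },
        "metastasis": met_block,
        "statistics": stats_block,
        "preprocessing": {
            "excluded_spots": dict(cm.excluded_spots),
            "admixed_spots": [f.spot_id for f in prep.admixture_flags],
            "n_homoplasy_flips": prep.n_homoplasy_flips,
            "public_loci": sorted(cm.public_loci),
            "dropped_loci": sorted(cm.dropped_loci),
            "audit": cm.audit,
        },
    }
    return _jsonable(report)


def _statistics_block(
    vafs: VAFMatrix,
    cm,
    subclones: Sequence[Subclone],
    tree: CloneTree,
    cfg: PipelineConfig,
) -> dict:
    spot_to_sub = {
        s.spot_id: sc.subclone_id for sc in subclones for s in sc.member_spots
    }
    primary = [s for s in vafs.spots if s.is_primary and s.spot_id in spot_to_sub]

    block: dict = {}
    for region, label in (("S", "superficial"), ("I", "invasive")):
        members = {s.spot_id: spot_to_sub[s.spot_id] for s in primary
                   if s.phenotype == region}
        if len(members) >= 2:
            census = SubcloneCensus.from_spots(label, members)
            block[f"gini_simpson_{label}"] = gini_simpson(census).gs
        else:
            block[f"gini_simpson_{label}"] = None
    all_members = {s.spot_id: spot_to_sub[s.spot_id] for s in primary}
    if len(all_members) >= 2:
        block["gini_simpson_tumor"] = gini_simpson(
            SubcloneCensus.from_spots("tumor", all_members)
        ).gs

    frac, n_contig, n_elig = contiguity_fraction(
        primary, spot_to_sub, radius_mm=cfg.adjacency_radius_mm
    )
    block["contiguity"] = {
        "fraction": None if n_elig == 0 else frac,
        "n_contiguous": n_contig,
        "n_eligible": n_elig,
    }

    # spatial vs genetic distance per slide
    genotypes = {}
    binary, idx = cm.effective_binary()
    for row, i in enumerate(idx):
        genotypes[cm.spots[i].spot_id] = binary[row, :]
    corr = {}
    by_slide: dict[str, list] = {}
    for s in primary:
        by_slide.setdefault(s.slide_id, []).append(s)
    for slide, members in sorted(by_slide.items()):
        labelled = [s for s in members if s.spot_id in genotypes]
        if len(labelled) >= 3:
            corr[slide] = spatial_genetic_correlation(labelled, genotypes)
        else:
            corr[slide] = None
    block["spatial_genetic_pearson"] = corr

    # normalized distances between spatially adjacent subclones
    adj_dists = []
    if len(tree.tips()) >= 3:
        pairs = set()
        for slide, members in by_slide.items():
            for a in members:
                for b in members:
                    if a.spot_id >= b.spot_id:
                        continue
                    da = spot_to_sub.get(a.spot_id)
                    db = spot_to_sub.get(b.spot_id)
                    if da is None or db is None or da == db:
                        continue
                    d2 = (a.x_mm - b.x_mm) ** 2 + (a.y_mm - b.y_mm) ** 2
                    if d2 <= cfg.adjacency_radius_mm ** 2:
                        pairs.add(tuple(sorted((da, db))))
        adj_dists = [normalized_adjacency_distance(tree, a, b) for a, b in sorted(pairs)]
    block["adjacent_subclone_distances"] = adj_dists
    if len(adj_dists) >= 2:
        stat, p = ks_uniform(adj_dists)
        block["adjacency_ks_uniform"] = {"statistic": stat, "pvalue": p}
    else:
        block["adjacency_ks_uniform"] = None

    sub_slides = {}
    for sc in subclones:
        slides = {s.slide_id for s in sc.member_spots if s.is_primary}
        if slides:
            sub_slides[sc.subclone_id] = slides
    wb = within_between_slide_distances(tree, sub_slides) if len(tree.tips()) >= 3 else None
    block["within_between_slides"] = (
        None if wb is None else {
            "within": wb.within, "between": wb.between,
            "ranksum_statistic": wb.statistic, "ranksum_pvalue": wb.pvalue,
        }
    )
    return block


def run_pipeline(vafs: VAFMatrix, cfg: PipelineConfig | None = None) -> dict[str, dict]:
    """Analyze every tumor present in the matrix; returns reports keyed
    by tumor id."""
    cfg = cfg or PipelineConfig()
    tumor_ids = sorted({s.tumor_id for s in vafs.spots})
    if not tumor_ids:
        raise ValueError("no spots after metadata intersection")
    reports = {}
    for tid in tumor_ids:
        sub = vafs.subset_spots([s.spot_id for s in vafs.spots if s.tumor_id == tid])
        try:
            reports[tid] = analyze_tumor(sub, cfg)
        except Exception as exc:
            raise RuntimeError(f"tumor {tid}: pipeline failed") from exc
    return reports


# ---------------------------------------------------------------------------
# Study-level census
# ---------------------------------------------------------------------------

def report_to_summary_row(report: Mapping, is_carcinoma: bool = True) -> StudySummaryRow:
    """Condense a per-tumor report into a census row."""
    counts = {"S": 0, "I": 0, "S-I": 0}
    for sc in report["subclones"]:
        pc = sc.get("phenotype_class")
        if pc in counts:
            counts[pc] += 1
    inv = report["invasion"]
    has_inv = bool(inv["invading_subclones"])

    def yn(val) -> str:
        if val is None:
            return "NA"
        return "yes" if val else "no"

    return StudySummaryRow(
        tumor_id=report["tumor_id"],
        n_spots=report["n_spots_total"],
        n_loci=report["n_loci"],
        n_subclones=report["n_subclones"],
        pheno_s=counts["S"],
        pheno_i=counts["I"],
        pheno_si=counts["S-I"],
        monophyletic_inv=yn(inv["monophyletic"]),
        early_inv=yn(inv["early_invasion"] if has_inv else None),
        multiclonal_inv=yn(inv["n_events"] >= 2 if has_inv else None),
        n_invasion_events=inv["n_events"] if has_inv else None,
        is_carcinoma=is_carcinoma,
    )


def summarize_study(rows: Sequence[StudySummaryRow]) -> dict:
    """Study-wide marginals from per-tumor census rows."""
    if not rows:
        raise ValueError("no rows")
    carcinomas = [r for r in rows if r.is_carcinoma]
    multiclonal_events = [
        r.n_invasion_events for r in rows
        if r.multiclonal_inv == "yes" and r.n_invasion_events is not None
    ]
    mixed_rows = [r for r in carcinomas if r.pheno_i + r.pheno_si > 0]
    mixed_num = sum(r.pheno_si for r in mixed_rows)
    mixed_den = sum(r.pheno_s + r.pheno_i + r.pheno_si for r in mixed_rows)
    return {
        "n_tumors": len(rows),
        "n_carcinomas": len(carcinomas),
        "total_spots": sum(r.n_spots for r in rows),
        "total_loci": sum(r.n_loci for r in rows),
        "median_panel_loci": float(pystats.median(r.n_loci for r in rows)),
        "median_subclones_per_tumor": float(pystats.median(r.n_subclones for r in rows)),
        "phenotype_totals": {
            "S": sum(r.pheno_s for r in rows),
            "I": sum(r.pheno_i for r in rows),
            "S-I": sum(r.pheno_si for r in rows),
        },
        "mixed_phenotype": {
            "numerator": mixed_num,
            "denominator": mixed_den,
            "percent": round(100 * mixed_num / mixed_den, 1) if mixed_den else None,
        },
        "monophyletic_carcinomas": sum(
            1 for r in carcinomas if r.monophyletic_inv == "yes"
        ),
        "multiclonal_carcinomas": sum(
            1 for r in carcinomas if r.multiclonal_inv == "yes"
        ),
        "early_invasion_carcinomas": sum(
            1 for r in carcinomas if r.early_inv == "yes"
        ),
        "median_invasion_events_multiclonal": (
            float(pystats.median(multiclonal_events)) if multiclonal_events else None
        ),
    }


# ---------------------------------------------------------------------------
# Report schema (structural validation; shipped in package data)
# ---------------------------------------------------------------------------

def _load_schema() -> dict:
    ref = resources.files("phylogeo").joinpath("data/report_schema.json")
    return json.loads(ref.read_text())


def validate_report(report: Mapping, schema: Mapping | None = None, path: str = "$") -> None:
    """Structural validation of a report against the shipped schema.

    Checks required keys and basic JSON types recursively; raises
    ValueError with the offending path on mismatch.
    """
    schema = schema if schema is not None else _load_schema()
    typ = schema.get("type")
    typemap = {"object": dict, "array": list, "string": str, "boolean": bool}
    if typ in typemap and not isinstance(report, typemap[typ]):
        raise ValueError(f"{path}: expected {typ}, got {type(report).__name__}")
    if typ in ("number", "integer") and not isinstance(report, (int, float)):
        raise ValueError(f"{path}: expected {typ}")
    if typ == "object":
        for key in schema.get("required", []):
            if key not in report:
                raise ValueError(f"{path}: missing required key {key!r}")
        for key, sub in schema.get("properties", {}).items():
            if key in report and report[key] is not None:
                validate_report(report[key], sub, f"{path}.{key}")
    if typ == "array":
        sub = schema.get("items")
        if sub:
            for i, item in enumerate(report):
                validate_report(item, sub, f"{path}[{i}]")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set, frozenset)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, float) and (obj != obj):
        return None
    return obj


# ---------------------------------------------------------------------------
# Command line
# ---------------------------------------------------------------------------

@click.group()
@click.option("--log-level", default="WARNING", show_default=True)
def cli(log_level: str) -> None:
    """Phylogeography of tumor invasion from microdissected spot VAFs."""
    logging.basicConfig(level=getattr(logging, log_level.upper(), logging.WARNING))


def _load_inputs(vaf, meta, config, seed) -> tuple[VAFMatrix, PipelineConfig]:
    cfg = PipelineConfig.from_file(config) if config else PipelineConfig()
    if seed is not None:
        cfg = cfg.with_seed(seed)
    return read_vaf_table(vaf, meta), cfg


_common = [
    click.option("--vaf", required=True, type=click.Path(exists=True)),
    click.option("--meta", required=True, type=click.Path(exists=True)),
    click.option("--config", type=click.Path(exists=True)),
    click.option("--seed", type=int, default=None),
    click.option("--out-dir", type=click.Path(), default="."),
]


def _with_common(fn):
    for opt in reversed(_common):
        fn = opt(fn)
    return fn


@cli.command()
@_with_common
def call(vaf, meta, config, seed, out_dir):
    """Genotype spots: calls, subclones and the preprocessing audit."""
    vm, cfg = _load_inputs(vaf, meta, config, seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    prep = preprocess(vm, cfg)
    cm = prep.call_matrix
    with open(out / "calls.tsv", "w") as fh:
        fh.write("spot_id\t" + "\t".join(cm.locus_ids) + "\n")
        for i, sid in enumerate(cm.spot_ids):
            codes = {1: "1", 0: "0", -1: "NA"}
            fh.write(sid + "\t" + "\t".join(codes[int(c)] for c in cm.calls[i]) + "\n")
    with open(out / "subclones.tsv", "w") as fh:
        fh.write("subclone_id\tn_spots\tmember_spots\tmutations\n")
        for sc in prep.subclones:
            muts = ",".join(cm.locus_ids[j] for j in sorted(sc.mutations))
            members = ",".join(s.spot_id for s in sc.member_spots)
            fh.write(f"{sc.subclone_id}\t{len(sc.member_spots)}\t{members}\t{muts}\n")
    (out / "audit.json").write_text(json.dumps(_jsonable(cm.audit), indent=2) + "\n")
    click.echo(f"{len(prep.subclones)} subclones; audit in {out / 'audit.json'}")


@cli.command()
@_with_common
def tree(vaf, meta, config, seed, out_dir):
    """Build the clone tree with bootstrap supports (Newick)."""
    vm, cfg = _load_inputs(vaf, meta, config, seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    prep = preprocess(vm, cfg)
    t = build_perfect_phylogeny(prep.subclones, prep.call_matrix.locus_ids)
    boot = bootstrap_support(prep.subclones, cfg, tree=t,
                             locus_ids=prep.call_matrix.locus_ids)
    write_newick(t, out / "tree.nwk", support=boot.support)
    click.echo(str(out / "tree.nwk"))


@cli.command()
@_with_common
def invade(vaf, meta, config, seed, out_dir):
    """Invasion report: monophyly, event count, timing."""
    vm, cfg = _load_inputs(vaf, meta, config, seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    reports = run_pipeline(vm, cfg)
    doc = {tid: r["invasion"] for tid, r in reports.items()}
    (out / "invasion.json").write_text(json.dumps(doc, indent=2) + "\n")
    click.echo(str(out / "invasion.json"))


@cli.command()
@_with_common
def stats(vaf, meta, config, seed, out_dir):
    """Diversity / distance / contiguity statistics."""
    vm, cfg = _load_inputs(vaf, meta, config, seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    reports = run_pipeline(vm, cfg)
    doc = {tid: r["statistics"] for tid, r in reports.items()}
    (out / "stats.json").write_text(json.dumps(doc, indent=2) + "\n")
    click.echo(str(out / "stats.json"))


@cli.command()
@_with_common
def report(vaf, meta, config, seed, out_dir):
    """Full per-tumor report (validated against the shipped schema)."""
    vm, cfg = _load_inputs(vaf, meta, config, seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    reports = run_pipeline(vm, cfg)
    for rep in reports.values():
        validate_report(rep)
    (out / "report.json").write_text(json.dumps(reports, indent=2) + "\n")
    click.echo(str(out / "report.json"))


@cli.command()
@click.option("--seed", type=int, default=0, show_default=True)
@click.option("--mode", type=click.Choice(["bottleneck", "multiclonal"]),
              default="multiclonal", show_default=True)
@click.option("--out-dir", type=click.Path(), default=".")
def simulate(seed, mode, out_dir):
    """Generate a synthetic tumor section (VAF table + truth)."""
    cfg = SimConfig(mode=mode, rng_seed=seed)
    sim = simulate_tumor(cfg)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_vaf_table(sim.vafs, out / "vaf.tsv", out / "meta.tsv", dialect="long")
    sim.truth.to_json(out / "truth.json")
    click.echo(f"{len(sim.vafs.spots)} spots written to {out}")


@cli.command()
@click.option("--table1", "use_packaged", is_flag=True,
              help="Summarize the packaged 12-tumor census table.")
@click.option("--rows", type=click.Path(exists=True),
              help="Summarize a census TSV instead.")
@click.option("--out", type=click.Path(), default=None)
def summarize(use_packaged, rows, out):
    """Study-level marginals from a per-tumor census table."""
    if not use_packaged and not rows:
        raise click.UsageError("pass --table1 or --rows PATH")
    summary = summarize_study(load_study_summary(rows))
    text = json.dumps(summary, indent=2)
    if out:
        Path(out).write_text(text + "\n")
    click.echo(text)


if __name__ == "__main__":
    cli()
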