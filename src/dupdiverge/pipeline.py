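"""End-to-end pipeline orchestration with a reproducibility manifest.

The config is a YAML mapping with one section per enabled stage; every
threshold defaults to the package-wide defaults, and all outputs land in one
run directory.  Re-running with the same config and seed reproduces
byte-identical TSV outputs (floats are printed at fixed precision).
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .io_models import read_catalog_tsv, read_fasta, read_gff3, read_newick
from .tandem import big_clusters, cluster_tandem, density_track, summarize_tandem
from .reconcile import aggregate_histories, lca_reconcile
from .selection import pairwise_dnds, sliding_window
from .structdiv import build_correspondence, classify_pair, pair_report
from .dotplot import call_repeats, self_dot_matrix
from .expression import (cluster_stage_patterns, pair_expression_divergence,
                         zscore_profiles)

log = logging.getLogger(__name__)

FLOAT_FMT = "%.6g"


class InputError(ValueError):
    """Missing or malformed stage input (CLI exit code 1)."""


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _write(df: pd.DataFrame, path: Path) -> dict:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)
    return {"path": str(path), "rows": int(len(df)), "sha256": _digest(path)}


def run_all(config: dict | str | Path, out_dir: str | Path, seed: int = 0) -> dict:
    """Execute the enabled stages in dependency order; returns the manifest.

    ``config`` maps stage names (tandem, reconcile, structdiv, dotplot, dnds,
    expression) to their input paths and parameters.  Inputs for every enabled
    stage are validated before any stage runs.
    """
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = [s for s in ("tandem", "reconcile", "structdiv", "dotplot", "dnds",
                          "expression") if s in config]
    # validate all inputs up front
    input_digests = {}
    for stage in stages:
        for key, val in config[stage].items():
            if key.endswith(("_path", "_file", "_dir")) or key in (
                    "gff", "fasta", "catalog", "family", "matrix", "pairs",
                    "genetrees", "speciestree"):
                p = Path(val)
                if not p.exists():
                    raise InputError(f"{stage}: input {key}={val} does not exist")
                if p.is_file():
                    input_digests[f"{stage}.{key}"] = _digest(p)

    manifest = {
        "tool_version": __version__,
        "seed": seed,
        "config": config,
        "inputs": input_digests,
        "outputs": {},
    }

    if "tandem" in config:
        c = config["tandem"]
        if "catalog" in c:
            catalog = read_catalog_tsv(c["catalog"])
        else:
            _, catalog = read_gff3(c["gff"])
        family = [l.strip() for l in Path(c["family"]).read_text().splitlines() if l.strip()]
        tcs = cluster_tandem(catalog, family, max_gap=int(c.get("max_gap", 20)))
        rows = [
            {"cluster_id": i, "chrom": cl.chrom, "n_members": len(cl.members),
             "start": cl.span[0] + 1, "end": cl.span[1],
             "members": ",".join(cl.members)}
            for i, cl in enumerate(tcs.clusters)
        ]
        manifest["outputs"]["tandem_clusters"] = _write(
            pd.DataFrame(rows, columns=["cluster_id", "chrom", "n_members",
                                        "start", "end", "members"]),
            out / "tandem_clusters.tsv")
        summ = summarize_tandem(tcs, len(family))
        manifest["outputs"]["tandem_summary"] = _write(
            pd.DataFrame([summ]), out / "tandem_summary.tsv")
        tracks = density_track(catalog, family,
                               window_bp=int(c.get("window_bp", 1_000_000)))
        dens = pd.DataFrame(
            [(t.chrom, i * t.window_bp, min((i + 1) * t.window_bp,
                                            catalog.chrom_lengths.get(t.chrom, (i + 1) * t.window_bp)), n)
             for t in tracks for i, n in enumerate(t.counts)],
            columns=["chrom", "start", "end", "count"])
        manifest["outputs"]["tandem_density"] = _write(dens, out / "tandem_density.bedgraph.tsv")

    if "reconcile" in config:
        c = config["reconcile"]
        stree = read_newick(c["speciestree"], species_leaves=True)
        gdir = Path(c["genetrees"])
        files = sorted(gdir.glob("*.nwk")) + sorted(gdir.glob("*.newick"))
        if not files:
            raise InputError(f"reconcile: no gene trees in {gdir}")
        recs = [lca_reconcile(read_newick(f), stree) for f in files]
        hist = aggregate_histories(recs, stree)
        manifest["outputs"]["reconcile_branches"] = _write(
            hist.to_frame(), out / "reconcile_branches.tsv")
        per_family = pd.DataFrame(
            [{"family": f.stem, "duplications": r.n_duplications,
              "losses": r.n_losses, "cost": r.cost} for f, r in zip(files, recs)])
        manifest["outputs"]["reconcile_families"] = _write(
            per_family, out / "reconcile_families.tsv")

    if "structdiv" in config:
        c = config["structdiv"]
        fasta = read_fasta(c["fasta"])
        models, _ = read_gff3(c["gff"], fasta=fasta)
        by_id = {m.gene_id: m for m in models}
        pairs = pd.read_csv(c["pairs"], sep="\t")
        rows = []
        for row in pairs.itertuples(index=False):
            a, b = by_id[str(row.gene_a)], by_id[str(row.gene_b)]
            corr = build_correspondence(a, b)
            events, primary = classify_pair(corr, a, b)
            rep = pair_report(events, a, b)
            rows.append({"gene_a": a.gene_id, "gene_b": b.gene_id,
                         "primary_mechanism": primary,
                         "n_events": len(events),
                         **{f"n_{m.lower()}": v for m, v in rep["mechanism_tally"].items()}})
        manifest["outputs"]["structdiv_pairs"] = _write(
            pd.DataFrame(rows), out / "structdiv_pairs.tsv")

    if "dotplot" in config:
        c = config["dotplot"]
        seqs = read_fasta(c["fasta"])
        rows = []
        for name, seq in seqs.items():
            mat = self_dot_matrix(seq, window=int(c.get("window", 30)),
                                  min_identity=float(c.get("min_identity", 0.6)),
                                  seq_id=name)
            for call in call_repeats(mat):
                rows.append({"seq_id": name, "start": call.region[0] + 1,
                             "end": call.region[1], "unit_length": call.unit_length,
                             "n_runs": call.n_offdiag_runs})
        manifest["outputs"]["dotplot_repeats"] = _write(
            pd.DataFrame(rows, columns=["seq_id", "start", "end", "unit_length",
                                        "n_runs"]),
            out / "dotplot_repeats.tsv")

    if "dnds" in config:
        c = config["dnds"]
        seqs = read_fasta(c["fasta"])
        pairs = pd.read_csv(c["pairs"], sep="\t")
        global_rows, window_rows = [], []
        for row in pairs.itertuples(index=False):
            a, b = seqs[str(row.gene_a)], seqs[str(row.gene_b)]
            res = pairwise_dnds(a, b)
            global_rows.append({"gene_a": row.gene_a, "gene_b": row.gene_b,
                                **res.as_dict()})
            track = sliding_window(a, b, window=int(c.get("window", 45)),
                                   step=int(c.get("step", 9)))
            wf = track.to_frame()
            wf.insert(0, "gene_a", row.gene_a)
            wf.insert(1, "gene_b", row.gene_b)
            window_rows.append(wf)
        manifest["outputs"]["dnds_pairs"] = _write(
            pd.DataFrame(global_rows), out / "dnds_pairs.tsv")
        manifest["outputs"]["dnds_windows"] = _write(
            pd.concat(window_rows, ignore_index=True), out / "dnds_windows.tsv")

    if "expression" in config:
        c = config["expression"]
        matrix = pd.read_csv(c["matrix"], sep="\t", index_col=0)
        profiles = zscore_profiles(matrix)
        zdf = pd.DataFrame({g: p.z for g, p in profiles.items()},
                           index=list(matrix.columns)).T
        zdf.insert(0, "gene_id", zdf.index)
        manifest["outputs"]["expression_z"] = _write(
            zdf, out / "expression_zscores.tsv")
        assign = cluster_stage_patterns(profiles, k=int(c.get("k", 8)), seed=seed)
        manifest["outputs"]["expression_clusters"] = _write(
            pd.DataFrame({"gene_id": list(assign), "cluster": list(assign.values())}),
            out / "expression_clusters.tsv")
        if "pairs" in c:
            pairs = pd.read_csv(c["pairs"], sep="\t")
            rows = []
            for row in pairs.itertuples(index=False):
                d = pair_expression_divergence(profiles[str(row.gene_a)],
                                               profiles[str(row.gene_b)])
                rows.append({"gene_a": row.gene_a, "gene_b": row.gene_b,
                             "divergent": d["divergent"], "r": d["r"],
                             "peak_a": d["peaks"][0], "peak_b": d["peaks"][1]})
            manifest["outputs"]["expression_pairs"] = _write(
                pd.DataFrame(rows), out / "expression_divergence.tsv")

    with open(out / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return manifest
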