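"""End-to-end orchestration: simulate/ingest -> features -> signatures ->
HRD -> clustering -> clinical -> actionability -> report bundle.

All randomness flows from a single root seed that is split per stage; the
seeds used are logged in the report, and reruns with the same config are
byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import actionability as act
from . import clinical as clin
from . import clustering as clust
from . import genome_features as gf
from . import hrd as hrd_mod
from . import signatures as sigs
from . import synthetic_data as synth
from . import variant_io as vio

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Thresholds and sizes for a full run; defaults match the method."""

    out_dir: str = "ocstrat_out"
    cohort_dir: str | None = None  # None -> simulate
    k: int = 7
    bootstrap_B: int = 200
    seed: int = 0
    min_purity: float = 0.20
    pfi_bin_days: int = 183
    hrd_mhdel_frac: float = 0.10
    hrd_shortdup_frac: float = 0.25
    min_contrib_frac: float = 0.05
    min_sample_frac: float = 0.10
    skip_clinical: bool = False
    skip_bootstrap: bool = False
    run_signature_selection: bool = False

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


@dataclass
class PipelineResult:
    report: dict
    feature_matrix: clust.FeatureMatrix
    cluster_result: clust.ClusterResult
    labels: dict[str, int]
    counts: dict[str, gf.ContextCounts]
    ploidy: dict[str, gf.PloidyProfile]
    hrd_calls: dict[str, hrd_mod.HrdCall]
    fits: dict[str, sigs.SignatureFit]
    summaries: list = field(default_factory=list)


def _load_cohort_dir(path: Path):
    manifest = pd.read_csv(path / "manifest.tsv", sep="\t")
    ref = vio.read_fasta(path / "reference.fasta")
    per_sample = {}
    for row in manifest.itertuples(index=False):
        per_sample[str(row.sample_id)] = (
            vio.read_small_variants(path / row.vcf),
            vio.read_sv(path / row.sv, dialect="tsv"),
            vio.read_cna(path / row.cna),
        )
    metas = vio.read_samples(path / "samples.tsv")
    clinical = (
        {r.sample_id: r for r in clin.read_clinical(path / "clinical.tsv")}
        if (path / "clinical.tsv").exists()
        else {}
    )
    events = {}
    ev_path = path / "gene_events.tsv"
    if ev_path.exists():
        df = pd.read_csv(ev_path, sep="\t")
        for sid in per_sample:
            events[sid] = act.SampleEvents(sid, [])
        for row in df.itertuples(index=False):
            events[str(row.sample_id)].events.append(
                act.GeneEvent(row.gene, row.event_type, bool(row.biallelic))
            )
    return ref, per_sample, metas, clinical, events


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the full stratification pipeline and write the report bundle."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    root = np.random.SeedSequence(config.seed)
    sim_seed, boot_seed = [int(s.generate_state(1)[0] % 2**31) for s in root.spawn(2)]

    if config.cohort_dir is None:
        log.info("simulating default synthetic cohort (seed %d)", sim_seed)
        cohort_dir = out / "cohort"
        cohort = synth.simulate_cohort(
            synth.CohortConfig(seed=sim_seed), out_dir=cohort_dir
        )
    else:
        cohort_dir = Path(config.cohort_dir)
    ref, per_sample, metas, clinical, events = _load_cohort_dir(Path(cohort_dir))

    metas = vio.filter_by_purity(metas, config.min_purity)
    kept = [m.sample_id for m in metas if m.sample_id in per_sample]

    counts: dict[str, gf.ContextCounts] = {}
    ploidy: dict[str, gf.PloidyProfile] = {}
    hrd_calls: dict[str, hrd_mod.HrdCall] = {}
    fits: dict[str, sigs.SignatureFit] = {}
    sbs_catalog = sigs.packaged_catalog("sbs")
    thresholds = hrd_mod.HrdThresholds(config.hrd_mhdel_frac, config.hrd_shortdup_frac)
    for sid in kept:
        variants, svs, segments = per_sample[sid]
        cc = gf.count_contexts(variants, svs, ref)
        counts[sid] = cc
        wgd = gf.call_wgd(segments)
        ploidy[sid] = gf.ploidy_fractions(segments, wgd=wgd)
        f_mh, f_dup = hrd_mod.hrd_features(cc, svs)
        hrd_calls[sid] = hrd_mod.classify_hrd_proxy(f_mh, f_dup, thresholds)
        fits[sid] = sigs.refit_signatures(cc.sbs96.astype(float), sbs_catalog)

    if config.run_signature_selection:
        selected = sigs.select_signatures(
            {s: counts[s].sbs96.astype(float) for s in kept},
            sbs_catalog,
            config.min_contrib_frac,
            config.min_sample_frac,
        )
        log.info("selected SBS signatures: %s", selected.names)
        fits = {
            s: sigs.refit_signatures(counts[s].sbs96.astype(float), selected)
            for s in kept
        }

    matrix = clust.build_feature_matrix({s: (counts[s], ploidy[s]) for s in kept})
    norm = clust.normalize_grouped(matrix)
    dist = clust.sample_distance(norm)
    result = clust.ward_cluster(dist, config.k)
    if not config.skip_bootstrap:
        result.bootstrap_p = clust.bootstrap_stability(
            norm, config.k, B=config.bootstrap_B, seed=boot_seed
        )
    result.pca_cumvar = clust.pca_cumvar(norm)
    labels = {sid: int(lab) for sid, lab in zip(kept, result.labels)}

    evidence = act.read_evidence()
    matches = {
        sid: act.match_actionable(events.get(sid, act.SampleEvents(sid, [])), evidence)
        for sid in kept
    }
    targetable = act.targetable_fraction_per_cluster(matches, labels)
    actionable_flags = {sid: bool(matches[sid]) for sid in kept}

    summaries = []
    if clinical and not config.skip_clinical:
        summaries = clin.summarize_cluster(
            labels, clinical, actionable_flags
        )

    report = _build_report(
        config, sim_seed, boot_seed, kept, counts, ploidy, hrd_calls, result,
        labels, targetable, summaries,
    )
    _write_outputs(out, kept, counts, ploidy, hrd_calls, fits, result, labels,
                   matches, report)
    return PipelineResult(
        report, matrix, result, labels, counts, ploidy, hrd_calls, fits, summaries
    )


def _build_report(config, sim_seed, boot_seed, kept, counts, ploidy, hrd_calls,
                  result, labels, targetable, summaries) -> dict:
    tmbs = {s: gf.compute_tmb(counts[s].total_snv_mnv_indel).tmb for s in kept}
    clusters = sorted(set(labels.values()))
    per_cluster = {}
    for c in clusters:
        members = [s for s in kept if labels[s] == c]
        per_cluster[str(c)] = {
            "n": len(members),
            "mean_tmb": float(np.mean([tmbs[s] for s in members])),
            "wgd_fraction": float(
                np.mean([ploidy[s].wgd for s in members])
            ),
            "hrd_deficient_fraction": float(
                np.mean([hrd_calls[s].status == "deficient" for s in members])
            ),
            "mean_sv_count": float(
                np.mean([counts[s].total_sv for s in members])
            ),
            "targetable_fraction": targetable.get(c, 0.0),
            "bootstrap_p": result.bootstrap_p.get(c),
        }
    for summary in summaries:
        blk = per_cluster.setdefault(str(summary.cluster), {})
        blk["clinical"] = {
            "favorable_n": summary.favorable_n,
            "poor_n": summary.poor_n,
            "missing_response_n": summary.missing_response_n,
            "one_year_survivors_n": summary.one_year_survivors_n,
            "at_risk_n": summary.at_risk_n,
            "one_year_percent": summary.one_year_percent,
            "histology": summary.histology_counts,
        }
    report = {
        "config": config.to_dict(),
        "seeds": {"simulate": sim_seed, "bootstrap": boot_seed},
        "n_samples": len(kept),
        "k": config.k,
        "pca_cumvar": [
            float(x)
            for x in (result.pca_cumvar if result.pca_cumvar is not None else [])
        ],
        "clusters": per_cluster,
    }
    if config.skip_clinical:
        report["clinical_skipped"] = True
    return report


def _write_outputs(out: Path, kept, counts, ploidy, hrd_calls, fits, result,
                   labels, matches, report) -> None:
    gf.context_table(counts).to_csv(out / "context_counts.tsv", sep="\t")
    rows = []
    for sid in kept:
        pp = ploidy[sid]
        call = hrd_calls[sid]
        rows.append(
            {
                "sample_id": sid,
                "cluster": labels[sid],
                "frac_haploid": pp.frac_haploid,
                "frac_diploid": pp.frac_diploid,
                "frac_polyploid": pp.frac_polyploid,
                "mean_ploidy": pp.mean_ploidy,
                "wgd": pp.wgd,
                "tmb": gf.compute_tmb(counts[sid].total_snv_mnv_indel).tmb,
                "hrd_status": call.status,
                "hrd_subtype": call.subtype,
                "f_mhdel": call.f_mhdel,
                "f_shortdup": call.f_shortdup,
            }
        )
    pd.DataFrame(rows).to_csv(out / "sample_annotations.tsv", sep="\t", index=False)
    sigs.contribution_table(fits).to_csv(out / "signature_contributions.tsv", sep="\t")
    pd.DataFrame(
        {"sample_id": kept, "cluster": [labels[s] for s in kept]}
    ).to_csv(out / "cluster_labels.tsv", sep="\t", index=False)
    clust.linkage_table(result.linkage).to_csv(out / "linkage.tsv", sep="\t", index=False)
    (out / "dendrogram.nwk").write_text(clust.to_newick(result.linkage, kept))
    act.match_table(matches).to_csv(out / "actionable_matches.tsv", sep="\t", index=False)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
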