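"""Stage orchestration: run the pipeline end-to-end on a dataset directory.

Every stage reads the plain-text outputs of earlier stages, writes
deterministic TSVs into a results directory, and stamps each table with the
producing stage and a config hash so reruns are checksummable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import diffexpr, discovery, downstream, io as tio, network, te_overlap
from .simulate import GroundTruth, SimulationConfig, simulate_dataset

STAGES = ("discover", "te", "de", "network", "hubs", "report")


@dataclass
class PipelineConfig:
    dataset_dir: str
    results_dir: str
    seed: int = 0
    discovery: discovery.DiscoveryConfig = field(default_factory=discovery.DiscoveryConfig)
    network: network.NetworkConfig = field(default_factory=network.NetworkConfig)

    def config_hash(self) -> str:
        payload = json.dumps(
            {
                "seed": self.seed,
                "discovery": asdict(self.discovery),
                "network": asdict(self.network),
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _write(frame: pd.DataFrame, path: Path, stage: str, cfg_hash: str, **kw) -> None:
    with open(path, "w") as fh:
        fh.write(f"# stage={stage} config={cfg_hash}\n")
        frame.to_csv(fh, sep="\t", **kw)


def run_simulate(cfg: SimulationConfig, dataset_dir: str | Path) -> None:
    simulate_dataset(cfg, dataset_dir)


class MissingStageError(RuntimeError):
    pass


def _need(path: Path, stage: str) -> Path:
    if not path.exists():
        raise MissingStageError(
            f"missing input {path.name}; run the '{stage}' stage (or simulate) first"
        )
    return path


def run_pipeline(cfg: PipelineConfig, stages: tuple[str, ...] = STAGES) -> dict:
    """Run the requested stages; returns the in-memory results bundle."""
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    ds = Path(cfg.dataset_dir)
    out = Path(cfg.results_dir)
    out.mkdir(parents=True, exist_ok=True)
    h = cfg.config_hash()
    bundle: dict = {}

    transcripts = tio.read_gtf(_need(ds / "transcripts.gtf", "simulate"))
    seqs = tio.read_fasta(_need(ds / "transcripts.fa", "simulate"))
    for t in transcripts:
        t.sequence = seqs[t.transcript_id]
        t.__post_init__()
    ann = tio.read_gff3_genes(_need(ds / "genes.gff3", "simulate"))
    te = tio.read_te_annotation(_need(ds / "te.bed", "simulate"), "bed")
    counts = pd.read_csv(_need(ds / "counts.tsv", "simulate"), sep="\t", index_col=0)
    samples = pd.read_csv(_need(ds / "samples.tsv", "simulate"), sep="\t", index_col=0)
    lengths = pd.Series({t.transcript_id: t.length for t in transcripts})
    fpkm = discovery.compute_fpkm(counts, lengths)
    bundle.update(transcripts=transcripts, ann=ann, te=te, counts=counts,
                  samples=samples, fpkm=fpkm)

    if "discover" in stages:
        evidence = discovery.load_evidence_tables(
            ds / "cpc2.tsv" if (ds / "cpc2.tsv").exists() else None,
            ds / "cnci.tsv" if (ds / "cnci.tsv").exists() else None,
            ds / "pfam.tsv" if (ds / "pfam.tsv").exists() else None,
        )
        records = discovery.run_discovery(
            transcripts, evidence, ann, fpkm, samples, cfg.discovery
        )
        bundle["records"] = records
        rec_frame = pd.DataFrame(
            {
                "transcript_id": [r.transcript_id for r in records],
                "passed": [r.passed for r in records],
                "rejection_reasons": [";".join(r.rejection_reasons) for r in records],
                "class_code": [r.class_code for r in records],
                "polyA_origin": [r.polyA_origin for r in records],
                "length_nt": [r.length_nt for r in records],
                "longest_orf_aa": [r.orf.longest_orf_aa for r in records],
                "max_fpkm": [r.max_fpkm for r in records],
            }
        ).set_index("transcript_id")
        _write(rec_frame, out / "lncrna_records.tsv", "discover", h)

    if "te" in stages:
        records = bundle.get("records")
        if records is None:
            raise MissingStageError("'te' needs the 'discover' stage in the same run")
        passed = {r.transcript_id for r in records if r.passed}
        results = [
            te_overlap.call_te_lncRNA(te_overlap.masked_fraction(t, te))
            for t in transcripts
            if t.transcript_id in passed
        ]
        bundle["te_results"] = results
        te_frame = pd.DataFrame(
            {
                "transcript_id": [r.transcript_id for r in results],
                "masked_fraction": [r.masked_fraction for r in results],
                "is_te_lncRNA": [r.is_te_lncRNA for r in results],
                "superfamily": [r.assigned_superfamily or "" for r in results],
            }
        ).set_index("transcript_id")
        _write(te_frame, out / "te_overlap.tsv", "te", h)
        if any(r.is_te_lncRNA for r in results):
            enr = te_overlap.superfamily_enrichment(results, te)
            _write(enr, out / "te_enrichment.tsv", "te", h, index=False)
            bundle["enrichment"] = enr
        te_flags = {r.transcript_id: r.is_te_lncRNA for r in results}
        summary = discovery.summary_table(records, te_flags)
        _write(summary, out / "discovery_summary.tsv", "te", h)
        bundle["summary"] = summary

    if "de" in stages:
        factors = diffexpr.median_ratio_size_factors(
            counts[samples.index[samples["library_type"] == "polyA"]]
        )
        specs = diffexpr.contrasts_from_samples(samples)
        results = {}
        for spec in specs:
            res = diffexpr.nb_wald_test(
                counts[spec.treatment + spec.control], spec, factors
            )
            res["call"] = diffexpr.call_de(res)
            results[spec.name] = res
            _write(res, out / f"de_{spec.name}.tsv", "de", h)
        bundle["de_results"] = results
        bundle["size_factors"] = factors

    if "network" in stages:
        polya = samples.index[samples["library_type"] == "polyA"]
        factors = diffexpr.median_ratio_size_factors(counts[polya])
        expressed = counts.index[(counts[polya] > 0).any(axis=1)]
        net = network.build_network(
            counts.loc[expressed, polya], factors, cfg.network
        )
        bundle["network"] = net
        _write(net.modules.to_frame(), out / "modules.tsv", "network", h)
        _write(net.eigengenes, out / "eigengenes.tsv", "network", h)
        if len(net.eigengenes):
            traits = network.trait_indicators(samples.loc[polya])
            mt = network.module_trait_correlation(net.eigengenes, traits, net.expr)
            bundle["module_trait"] = mt
            _write(mt.r, out / "module_trait_r.tsv", "network", h)

    if "hubs" in stages:
        net = bundle.get("network")
        if net is None:
            raise MissingStageError("'hubs' needs the 'network' stage in the same run")
        mt = bundle.get("module_trait")
        if mt is None:  # no modules survived: empty hub table
            hubs = network.find_hubs(
                net.modules, net.kme, net.kim,
                network.ModuleTraitResult(
                    r=pd.DataFrame(), p=pd.DataFrame(),
                    gs_r=pd.DataFrame(), gs_p=pd.DataFrame(),
                ),
                cfg.network,
            )
        else:
            classes = _classes_from_bundle(bundle)
            hubs = network.find_hubs(
                net.modules, net.kme, net.kim, mt, cfg.network, classes
            )
        bundle["hubs"] = hubs
        _write(hubs, out / "hubs.tsv", "hubs", h, index=False)

    if "report" in stages:
        _report(bundle, out, h, cfg)
    return bundle


def _classes_from_bundle(bundle: dict) -> dict[str, str]:
    classes: dict[str, str] = {}
    for r in bundle.get("records", []):
        classes[r.transcript_id] = "coding" if not r.passed else "lncRNA"
    for res in bundle.get("te_results", []):
        if res.is_te_lncRNA and classes.get(res.transcript_id) == "lncRNA":
            classes[res.transcript_id] = "TE_lncRNA"
    return classes


def _report(bundle: dict, out: Path, h: str, cfg: PipelineConfig) -> None:
    classes = _classes_from_bundle(bundle)
    if "de_results" in bundle and classes:
        sharing = diffexpr.de_overlap_summary(bundle["de_results"], classes)
        _write(sharing["counts"], out / "de_summary.tsv", "report", h, index=False)
        with open(out / "de_sharing.json", "w") as fh:
            json.dump(
                {
                    "intersections": sharing["intersections"],
                    "union_by_class": sharing["union_by_class"],
                    "union_total": sharing["union_total"],
                },
                fh,
                indent=1,
                sort_keys=True,
            )
    manifest = {
        "config_hash": h,
        "seed": cfg.seed,
        "stages": sorted(
            k for k in ("records", "te_results", "de_results", "network", "hubs")
            if k in bundle
        ),
    }
    with open(out / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
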