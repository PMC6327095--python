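"""End-to-end pipeline orchestration with seeded-run provenance.

A YAML run configuration drives simulate -> normalize -> variability ->
consensus clustering -> permutation DE -> target enrichment -> signature
extraction, writing every stage output plus a run manifest (config hash,
input digests, per-stage wall time, output list) for reproducibility.
"""

from __future__ import annotations

import hashlib
import json
import os
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import clustering, enrichment, io, preprocess, signatures, simulate

_SCHEMA: dict[str, set[str]] = {
    "": {"seed", "out_dir", "simulate", "inputs", "preprocess", "cluster",
         "enrich", "signature"},
    "simulate": {"n_cells", "n_mirnas", "n_genes", "targets_per_mirna",
                 "repression_strength", "repressor_mirna", "mirna_sd_log2",
                 "biological_sd_log2", "tech_sd_log2", "cluster_frac",
                 "cluster_effect_log2"},
    "inputs": {"mirna", "mrna", "targets", "probe_map"},
    "preprocess": {"mirna_floor", "mrna_floor"},
    "cluster": {"k_range", "iterations", "sample_frac", "de_k", "n_perm"},
    "enrich": {"mirna_id", "score_cutoff", "edges", "n_perm"},
    "signature": {"cutoff"},
}


class ConfigError(ValueError):
    """Invalid or incomplete run configuration."""


@dataclass
class RunConfig:
    """Validated pipeline configuration (unknown keys rejected)."""

    raw: dict
    seed: int
    out_dir: Path

    @classmethod
    def from_dict(cls, cfg: dict) -> "RunConfig":
        unknown = set(cfg) - _SCHEMA[""]
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        for section, allowed in _SCHEMA.items():
            if section and section in cfg:
                extra = set(cfg[section] or {}) - allowed
                if extra:
                    raise ConfigError(f"unknown keys in {section!r}: {sorted(extra)}")
        if "seed" not in cfg:
            raise ConfigError("config must set an explicit seed")
        if "out_dir" not in cfg:
            raise ConfigError("config must set out_dir")
        if "simulate" not in cfg and "inputs" not in cfg:
            raise ConfigError("config needs either a 'simulate' or an 'inputs' section")
        return cls(raw=cfg, seed=int(cfg["seed"]), out_dir=Path(cfg["out_dir"]))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
        if not isinstance(cfg, dict):
            raise ConfigError(f"{path}: config must be a YAML mapping")
        return cls.from_dict(cfg)

    def section(self, name: str) -> dict:
        return dict(self.raw.get(name) or {})


@dataclass
class RunManifest:
    version: str
    config_hash: str
    seed: int
    input_digests: dict[str, str] = field(default_factory=dict)
    stage_seconds: dict[str, float] = field(default_factory=dict)
    outputs: list[str] = field(default_factory=list)

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        tmp = path.with_suffix(".tmp")
        tmp.write_text(json.dumps(self.__dict__, indent=2, sort_keys=True) + "\n")
        os.replace(tmp, path)  # atomic on POSIX
        return path


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute every configured stage in order; abort on the first failure
    with the failing stage named."""
    from importlib.metadata import version as _pkg_version

    try:
        version = _pkg_version("halfcell")
    except Exception:
        version = "unknown"
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    cfg_bytes = json.dumps(config.raw, sort_keys=True, default=str).encode()
    manifest = RunManifest(version=version, seed=config.seed,
                           config_hash=hashlib.sha256(cfg_bytes).hexdigest())

    def stage(name):
        def deco(fn):
            t0 = time.perf_counter()
            try:
                result = fn()
            except Exception as exc:
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
            manifest.stage_seconds[name] = round(time.perf_counter() - t0, 4)
            return result
        return deco

    sim_cfg = config.section("simulate")
    inputs = config.section("inputs")

    @stage("load")
    def _load():
        if sim_cfg:
            n_mirnas = int(sim_cfg.get("n_mirnas", 30))
            n_genes = int(sim_cfg.get("n_genes", 2000))
            tpm = int(sim_cfg.get("targets_per_mirna", 50))
            table = simulate.generate_target_table(
                n_mirnas, n_genes, tpm, seed=config.seed
            )
            overrides = {}
            for key in ("n_cells", "biological_sd_log2", "tech_sd_log2",
                        "cluster_frac", "cluster_effect_log2"):
                if key in sim_cfg:
                    overrides[key] = sim_cfg[key]
            repressor = sim_cfg.get("repressor_mirna", "miR-001")
            strength = float(sim_cfg.get("repression_strength", 0.0))
            sc = simulate.default_config(
                seed=config.seed, n_mirnas=n_mirnas, n_genes=n_genes, **overrides
            )
            if "mirna_sd_log2" in sim_cfg:
                sc = simulate.SimConfig(**{
                    **sc.__dict__,
                    "mirna_sd_log2": tuple(
                        np.full(n_mirnas, float(sim_cfg["mirna_sd_log2"]))
                    ),
                })
            if strength > 0:
                edges = simulate.plant_repression(table, repressor, strength)
                sc = simulate.SimConfig(**{**sc.__dict__, "target_edges": edges})
            mirna, mrna, truth = simulate.generate_paired_profiles(sc)
            io.write_matrix(mirna, out / "mirna_fractions.tsv")
            io.write_matrix(mrna, out / "mrna_rpkm.tsv")
            io.write_target_table(table, out / "targets.tsv")
            truth_json = {
                "target_edges": [list(e) for e in truth.target_edges],
                "cluster_labels": truth.cluster_labels.tolist(),
            }
            (out / "ground_truth.json").write_text(
                json.dumps(truth_json, indent=2) + "\n"
            )
            return mirna, mrna, table
        mirna = io.read_matrix(inputs["mirna"], unit="fraction")
        mrna = io.read_matrix(inputs["mrna"], unit="rpkm")
        table = io.read_target_table(inputs["targets"])
        for key in ("mirna", "mrna", "targets"):
            manifest.input_digests[key] = _sha256(Path(inputs[key]))
        return mirna, mrna, table

    mirna, mrna, table = _load

    prep = config.section("preprocess")
    mirna_floor = float(prep.get("mirna_floor", preprocess.MIRNA_FLOOR))
    mrna_floor = float(prep.get("mrna_floor", preprocess.MRNA_FLOOR))

    @stage("normalize")
    def _norm():
        mi_log = preprocess.floor_and_log2(mirna, mirna_floor)
        mr_log = preprocess.floor_and_log2(mrna, mrna_floor)
        io.write_matrix(mi_log, out / "mirna_log2.tsv")
        io.write_matrix(mr_log, out / "mrna_log2.tsv")
        return mi_log, mr_log

    mi_log, mr_log = _norm

    @stage("variability")
    def _var():
        for name, mat in (("mirna", mi_log), ("mrna", mr_log)):
            preprocess.variability_profile(mat).to_csv(
                out / f"{name}_variability.tsv", sep="\t", index=False
            )

    _var

    clu = config.section("cluster")
    k_range = clu.get("k_range", [2, 3, 4, 5])
    de_k = int(clu.get("de_k", 2))

    @stage("cluster")
    def _cluster():
        res = clustering.consensus_cluster(
            mr_log, k_range=k_range,
            iterations=int(clu.get("iterations", 50)),
            sample_frac=float(clu.get("sample_frac", 0.8)),
            seed=config.seed,
        )
        for k, cm in res.consensus.items():
            cm.as_frame().to_csv(out / f"consensus_k{k}.tsv", sep="\t")
        labels = {str(k): a.labels.tolist() for k, a in res.labels.items()}
        (out / "cluster_labels.json").write_text(json.dumps(labels, indent=2) + "\n")
        return res

    cons = _cluster

    @stage("de")
    def _de():
        de = clustering.permutation_de(
            mr_log, cons.labels[de_k].labels,
            n_perm=int(clu.get("n_perm", 5000)), seed=config.seed,
        )
        de.to_csv(out / "de.tsv", sep="\t", index=False)
        return de

    _de

    enr = config.section("enrich")
    sig = config.section("signature")

    @stage("enrich")
    def _enrich():
        mirna_id = enr.get("mirna_id")
        if mirna_id is None:
            # default to the most abundant miRNA (largest mean fraction)
            mirna_id = mirna.data.mean(axis=1).idxmax()
        ranking = enrichment.correlate_to_mirna(
            mr_log, mi_log.data.loc[mirna_id].to_numpy(), mirna=str(mirna_id)
        )
        ranking.table.to_csv(out / "ranking.tsv", sep="\t", index=False)
        targets = enrichment.select_targets(
            table, str(mirna_id), float(enr.get("score_cutoff", enrichment.SCORE_CUTOFF))
        )
        rows = []
        if targets & set(ranking.genes):
            edges = tuple(float(e) for e in enr.get("edges", [4.0]))
            strata = enrichment.stratify_by_expression(targets, ranking, edges)
            strata = {"all": targets & set(ranking.genes), **strata}
            for name, members in strata.items():
                if not members or len(members) >= len(ranking.genes):
                    continue
                es = enrichment.es_permutation_p(
                    ranking, members, n_perm=int(enr.get("n_perm", 1000)),
                    seed=config.seed,
                )
                ks = enrichment.ks_compare(ranking, members)
                rows.append((name, len(members), es.es, es.p_perm, ks.d, ks.p))
        import pandas as pd

        pd.DataFrame(
            rows, columns=["stratum", "n_genes", "es", "es_p", "ks_d", "ks_p"]
        ).to_csv(out / "enrichment.tsv", sep="\t", index=False)
        return ranking

    ranking = _enrich

    @stage("signature")
    def _signature():
        pair = signatures.extract_signature(
            ranking, float(sig.get("cutoff", signatures.SIGNATURE_CUTOFF))
        )
        (out / "signature.json").write_text(json.dumps(
            {"mirna": pair.mirna, "cutoff": pair.cutoff,
             "up": pair.up, "down": pair.down}, indent=2) + "\n")
        if "probe_map" in inputs:
            pm = signatures.ProbeMap(io.read_probe_map(inputs["probe_map"]))
            if pair.up or pair.down:
                signatures.write_grp(pair, pm, out / "signature")

    _signature

    manifest.outputs = sorted(
        {str(p.relative_to(out)) for p in out.iterdir() if p.is_file()}
        | {"manifest.json"}
    )
    manifest.write(out / "manifest.json")
    return manifest
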