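"""End-to-end synthetic pipeline: simulate -> map -> signatures -> incidence
-> co-occurrence, driven by a schema-validated YAML configuration.

A single global seed fans out into per-stage child seeds via stable
hashing, so any stage rerun in isolation reproduces its output.  Every
tabular output carries a header line naming the tool version and the
SHA-256 hash of the configuration, and identical config+seed yields
byte-identical tables.
"""
from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from ._util import child_seed
from .cooccur import IncriminationRule, incriminate, permutation_test
from .incidence import (PresenceThresholds, call_presence, hierarchical_cluster,
                        incidence_matrix, quantify)
from .io import write_fasta, write_fastq, write_sam
from .mapper import AlignmentParams, build_index, map_library
from .signatures import RnaiThresholds, coverage_5prime, profile_pair
from .simulate import (GenomeSpec, PanelSimConfig, SmallRnaSimConfig, VirusModel,
                       make_genome, simulate_presence_panel,
                       simulate_small_rna_library)

log = logging.getLogger("viromesig")

RNAI_MODES = ("sirna", "pingpong", "both", "eve")

# Generative presets per RNAi regime; the status each should elicit.
_MODE_PRESETS: dict[str, dict[str, Any]] = {
    "sirna": dict(frac_sirna=0.8, frac_pirna=0.0, frac_noise=0.2),
    "pingpong": dict(frac_sirna=0.0, frac_pirna=0.8, frac_noise=0.2,
                     pingpong_prob=0.6, u1_bias=0.9, a10_bias=0.9),
    "both": dict(frac_sirna=0.4, frac_pirna=0.4, frac_noise=0.2,
                 pingpong_prob=0.6, u1_bias=0.9, a10_bias=0.9),
    "eve": dict(frac_sirna=0.0, frac_pirna=0.9, frac_noise=0.1,
                eve_mode=True, u1_bias=0.9),
}

MODE_EXPECTED_STATUS = {"sirna": "ACTIVE_SIRNA", "pingpong": "PIRNA_PINGPONG",
                        "both": "ACTIVE_SIRNA_PLUS_PIRNA", "eve": "EVE_LIKE"}

_SCHEMA: dict[str, Any] = {
    "seed": int,
    "output_dir": str,
    "simulate": {
        "n_libraries": int,
        "reads_per_library": int,
        "gc_fraction": float,
        "segment_dropout": float,
        "satellite_dependence": float,
        "contamination_rate": float,
        "viruses": [{
            "virus_id": str,
            "segment_lengths": [int],
            "satellites": [str],
            "prevalence": float,
            "rnai_mode": str,
        }],
    },
    "map": {"min_identity": float, "min_aligned_fraction": float,
            "max_mismatches": int, "min_read_len": int, "seed_k": int,
            "report": str},
    "signatures": {"n_min": int, "z_min": float, "window": [int],
                   "s_eve": float, "sirna_peak_fraction": float},
    "incidence": {"n_min": int, "breadth_min": float, "pseudocount": float},
    "cooccur": {"n_permutations": int, "alpha": float, "min_consistency": float,
                "min_positive_libraries": int},
}


class ConfigError(ValueError):
    pass


def _validate(node: Any, schema: Any, path: str = "") -> None:
    if isinstance(schema, dict):
        if not isinstance(node, dict):
            raise ConfigError(f"{path or 'config'}: expected a mapping")
        unknown = set(node) - set(schema)
        if unknown:
            raise ConfigError(f"{path or 'config'}: unknown key(s) {sorted(unknown)}")
        for key, value in node.items():
            _validate(value, schema[key], f"{path}.{key}" if path else key)
    elif isinstance(schema, list):
        if not isinstance(node, list):
            raise ConfigError(f"{path}: expected a list")
        for i, item in enumerate(node):
            _validate(item, schema[0], f"{path}[{i}]")
    else:
        if schema is float and isinstance(node, int) and not isinstance(node, bool):
            return
        if not isinstance(node, schema) or isinstance(node, bool):
            raise ConfigError(f"{path}: expected {schema.__name__}, "
                              f"got {type(node).__name__}")


def validate_config(config: dict) -> dict:
    _validate(config, _SCHEMA)
    for req in ("seed", "simulate"):
        if req not in config:
            raise ConfigError(f"missing required key '{req}'")
    sim = config["simulate"]
    if not sim.get("viruses"):
        raise ConfigError("simulate.viruses must be non-empty")
    for i, v in enumerate(sim["viruses"]):
        for req in ("virus_id", "segment_lengths", "rnai_mode"):
            if req not in v:
                raise ConfigError(f"simulate.viruses[{i}]: missing '{req}'")
        if v["rnai_mode"] not in RNAI_MODES:
            raise ConfigError(
                f"simulate.viruses[{i}].rnai_mode: must be one of {RNAI_MODES}")
    return config


def load_config(path) -> dict:
    with open(path) as fh:
        return validate_config(yaml.safe_load(fh))


def config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def demo_config(seed: int = 11, output_dir: str = "viromesig_demo") -> dict:
    """A small, complete end-to-end configuration."""
    return {
        "seed": seed,
        "output_dir": output_dir,
        "simulate": {
            "n_libraries": 10,
            "reads_per_library": 2000,
            "gc_fraction": 0.45,
            "segment_dropout": 0.0,
            "satellite_dependence": 1.0,
            "contamination_rate": 0.0,
            "viruses": [
                {"virus_id": "binegev_like", "segment_lengths": [7600, 4600],
                 "satellites": [], "prevalence": 0.5, "rnai_mode": "sirna"},
                {"virus_id": "phasma_like", "segment_lengths": [4000],
                 "satellites": [], "prevalence": 0.6, "rnai_mode": "pingpong"},
                {"virus_id": "eve_element", "segment_lengths": [2000],
                 "satellites": [], "prevalence": 0.5, "rnai_mode": "eve"},
            ],
        },
        "map": {}, "signatures": {}, "incidence": {},
        "cooccur": {"n_permutations": 499},
    }


def small_rna_config(mode: str, n_reads: int, seed: int,
                     **overrides) -> SmallRnaSimConfig:
    if mode not in _MODE_PRESETS:
        raise ValueError(f"unknown rnai_mode '{mode}'")
    kwargs = dict(_MODE_PRESETS[mode])
    kwargs.update(overrides)
    return SmallRnaSimConfig(n_reads=n_reads, seed=seed, **kwargs)


def _write_table(df: pd.DataFrame, path: Path, chash: str, index=False,
                 index_label=None) -> None:
    with open(path, "w") as fh:
        fh.write(f"# viromesig {__version__} config={chash}\n")
        df.to_csv(fh, sep="\t", index=index, index_label=index_label)


def run_pipeline(config: dict, output_dir: str | Path | None = None) -> dict:
    """Run the full synthetic pipeline; returns a summary of outputs."""
    config = validate_config(config)
    chash = config_hash(config)
    outdir = Path(output_dir or config.get("output_dir", "viromesig_out"))
    outdir.mkdir(parents=True, exist_ok=True)
    seed = config["seed"]
    sim_cfg = config["simulate"]
    map_params = AlignmentParams(**config.get("map", {}))
    sig_kwargs = dict(config.get("signatures", {}))
    if "window" in sig_kwargs:
        sig_kwargs["window"] = tuple(sig_kwargs["window"])
    thresholds = RnaiThresholds(**sig_kwargs)
    inc_cfg = dict(config.get("incidence", {}))
    pseudocount = inc_cfg.pop("pseudocount", 1.0)
    presence_thresholds = PresenceThresholds(**inc_cfg)
    co_cfg = dict(config.get("cooccur", {}))
    n_perms = co_cfg.pop("n_permutations", 499)
    rule = IncriminationRule(**co_cfg)

    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)

    # --- stage 1: genomes -------------------------------------------------
    genomes: dict[str, list] = {}
    virus_models = []
    for v in sim_cfg["viruses"]:
        vid = v["virus_id"]
        spec = GenomeSpec(segment_lengths=tuple(v["segment_lengths"]),
                          gc_fraction=sim_cfg.get("gc_fraction", 0.5),
                          seed=child_seed(seed, f"genome:{vid}"),
                          id_prefix=f"{vid}_s")
        genomes[vid] = make_genome(spec)
        seg_ids = tuple(rec.id for rec in genomes[vid])
        sats = tuple(f"{vid}_s{int(s)}" if str(s).isdigit() else s
                     for s in v.get("satellites", []))
        virus_models.append(VirusModel(virus_id=vid, segment_ids=seg_ids,
                                       satellite_ids=sats,
                                       prevalence=v.get("prevalence", 0.5)))
        write_fasta(genomes[vid], outdir / f"{vid}.fasta")
    log.info("generated %d virus genomes", len(genomes))

    # --- stage 2: presence panel -----------------------------------------
    panel_cfg = PanelSimConfig(
        n_libraries=sim_cfg["n_libraries"], virus_models=tuple(virus_models),
        segment_dropout=sim_cfg.get("segment_dropout", 0.0),
        satellite_dependence=sim_cfg.get("satellite_dependence", 1.0),
        contamination_rate=sim_cfg.get("contamination_rate", 0.0),
        seed=child_seed(seed, "panel"))
    seg_presence, _seg_rpkm, virus_truth = simulate_presence_panel(panel_cfg)
    _write_table(seg_presence.astype(int), outdir / "segment_presence.tsv",
                 chash, index=True, index_label="segment")

    # --- stage 3: per virus-library small RNA + mapping + signatures ------
    n_reads = sim_cfg["reads_per_library"]
    modes = {v["virus_id"]: v["rnai_mode"] for v in sim_cfg["viruses"]}
    call_rows, quants, presence_calls = [], [], {}
    for vid, model in zip(genomes, virus_models):
        index = build_index(genomes[vid], k=map_params.seed_k)
        seg_lengths = {rec.id: len(rec.seq) for rec in genomes[vid]}
        genome_len = sum(seg_lengths.values())
        for lib in virus_truth.columns:
            infected = bool(virus_truth.loc[vid, lib])
            if infected:
                rcfg = small_rna_config(
                    modes[vid], n_reads,
                    child_seed(seed, f"reads:{vid}:{lib}"))
                reads, labels = simulate_small_rna_library(
                    genomes[vid], rcfg, id_prefix=f"{lib}_{vid}_r")
                alignments, summary = map_library(reads, index, map_params)
                read_seqs = {rec.id: str(rec.seq) for rec in reads}
                _prof, _bias, _pp, call = profile_pair(
                    alignments, read_seqs, thresholds)
                covered = 0
                for sid, ln in seg_lengths.items():
                    cov = coverage_5prime(alignments, sid, ln)
                    covered += int(((cov.plus + cov.minus) > 0).sum())
                breadth = covered / genome_len
                mapped = summary.n_mapped
                if lib == virus_truth.columns[0]:
                    write_fastq(reads, outdir / f"{vid}_{lib}.fastq")
                    write_sam(alignments, seg_lengths, read_seqs,
                              outdir / f"{vid}_{lib}.sam")
            else:
                mapped, breadth = 0, 0.0
                call = None
            quant = quantify(vid, lib, mapped, max(n_reads, 1), genome_len,
                             breadth=breadth)
            present, reason = call_presence(quant, thresholds=presence_thresholds)
            presence_calls[(vid, lib)] = present
            quants.append(quant)
            call_rows.append({
                "virus_id": vid, "library_id": lib, "infected_truth": infected,
                "mapped_reads": mapped, "rpkm": round(quant.rpkm, 4),
                "breadth": round(breadth, 4), "present": present,
                "presence_reason": reason,
                "rnai_truth": modes[vid] if infected else "",
                "rnai_call": call.status if call else "NOT_DETECTED",
            })
    calls_df = pd.DataFrame(call_rows)
    _write_table(calls_df, outdir / "rnai_calls.tsv", chash)

    # --- stage 4: incidence matrix + clustering ---------------------------
    matrix = incidence_matrix(quants, presence_calls,
                              thresholds=presence_thresholds,
                              pseudocount=pseudocount)
    _write_table(matrix.log_abundance.round(6), outdir / "incidence_log_rpkm.tsv",
                 chash, index=True, index_label="virus")
    _write_table(matrix.presence.astype(int), outdir / "incidence_presence.tsv",
                 chash, index=True, index_label="virus")
    newicks = {}
    if matrix.log_abundance.shape[0] >= 2:
        dend = hierarchical_cluster(matrix.log_abundance, "rows")
        newicks["rows"] = dend.to_newick()
        (outdir / "virus_dendrogram.nwk").write_text(newicks["rows"] + "\n")
    if matrix.log_abundance.shape[1] >= 2:
        dend = hierarchical_cluster(matrix.log_abundance, "columns")
        newicks["columns"] = dend.to_newick()
        (outdir / "library_dendrogram.nwk").write_text(newicks["columns"] + "\n")

    # --- stage 5: co-occurrence for multi-segment viruses -----------------
    co_rows = []
    for model in virus_models:
        if len(model.segment_ids) < 2:
            continue
        stats = permutation_test(seg_presence, model.segment_ids,
                                 n_permutations=n_perms,
                                 seed=child_seed(seed, f"perm:{model.virus_id}"))
        decision = incriminate(stats, rule)
        co_rows.append({
            "virus_id": model.virus_id,
            "segments": ",".join(model.segment_ids),
            "n_any": stats.n_any, "n_all": stats.n_all,
            "consistency": stats.consistency,
            "permutation_p": stats.permutation_p,
            "decision": decision.decision,
        })
    if co_rows:
        _write_table(pd.DataFrame(co_rows), outdir / "cooccurrence.tsv", chash)

    log.info("pipeline complete; outputs in %s", outdir)
    return {"output_dir": str(outdir), "config_hash": chash,
            "rnai_calls": calls_df, "incidence": matrix,
            "cooccurrence": pd.DataFrame(co_rows), "newicks": newicks}
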