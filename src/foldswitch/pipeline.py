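"""End-to-end run orchestration: embed -> design -> variants -> linkage.

A run is driven by a single nested config (YAML on disk, dict in
memory).  Unknown keys are rejected before any stage executes, every
source of randomness is funnelled through named seeds, and a manifest
echoing the fully resolved config plus package version is written so a
run can be repeated exactly from the manifest alone (outputs carry no
timestamps).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import yaml

from . import __version__
from .design import (
    CANDIDATE_ALPHABET,
    MAX_SWEEPS,
    EnergyModel,
    apply_variant,
    coarse_energy,
    find_conflict_clusters,
    merge_initial,
    optimize_nonoverlap,
    resolve_cluster,
    truncate_to_short,
)
from .embedding import enumerate_embeddings, rank_embeddings, score_conflicts
from .errors import ConfigurationError, DomainError
from .fold_model import FoldTemplate, write_fasta
from .synthetic import ToyFoldSpec, make_fold_pair
from .thermo import celsius_to_kelvin, switch_free_energy, three_state_populations

logger = logging.getLogger(__name__)

#: Allowed config keys, nested. ``None`` marks a leaf.
CONFIG_SCHEMA = {
    "seed": None,
    "log_level": None,
    "fold_pair": {
        "source": None,  # "synthetic" or "files"
        "long_json": None,
        "short_json": None,
        "synthetic": {
            "long_length": None,
            "short_length": None,
            "anchor_length": None,
            "planted_offset": None,
            "n_planted_conflicts": None,
            "decoy_conflict_floor": None,
        },
    },
    "anchor": None,
    "design": {
        "candidate_alphabet": None,
        "max_sweeps": None,
        "run_nonoverlap": None,
        "weights": None,
    },
    "variants": None,
    "thermo": {
        "dg_short": None,
        "dg_long": None,
        "temperature_C": None,
    },
}

DEFAULT_CONFIG = {
    "seed": 0,
    "log_level": "INFO",
    "fold_pair": {"source": "synthetic", "synthetic": {}},
    "anchor": ["α1", "α1"],
    "design": {
        "candidate_alphabet": CANDIDATE_ALPHABET,
        "max_sweeps": MAX_SWEEPS,
        "run_nonoverlap": True,
        "weights": [1.0, 1.0, 0.5],
    },
    "variants": [],
    "thermo": {"dg_short": None, "dg_long": None, "temperature_C": 25.0},
}


def validate_config(config: dict, schema: dict = CONFIG_SCHEMA, path: str = "") -> None:
    """Reject unknown keys anywhere in the nested config."""
    for key, value in config.items():
        if key not in schema:
            raise ConfigurationError(f"unknown config key {path + key!r}")
        sub = schema[key]
        if isinstance(sub, dict) and isinstance(value, dict):
            validate_config(value, sub, path + key + ".")


def _merge_defaults(config: dict, defaults: dict) -> dict:
    out = dict(defaults)
    for k, v in config.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge_defaults(v, out[k])
        else:
            out[k] = v
    return out


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    validate_config(cfg)
    return _merge_defaults(cfg, DEFAULT_CONFIG)


def resolve_config(config: dict | None) -> dict:
    cfg = config or {}
    validate_config(cfg)
    return _merge_defaults(cfg, DEFAULT_CONFIG)


def write_ranks_tsv(path, ranked) -> None:
    """TSV of ranked alignments: rank, offset, counts, severity, conflicts."""
    with open(path, "w") as fh:
        fh.write("rank\toffset\ttotal_count\ttotal_severity\tkind_matches\tconflicts\n")
        for rank, rep in enumerate(ranked, start=1):
            joined = ";".join(f"{c.long_position}:{c.kind}" for c in rep.conflicts)
            fh.write(
                f"{rank}\t{rep.embedding.offset}\t{rep.total_count}\t"
                f"{rep.total_severity:g}\t{rep.embedding.kind_matches}\t{joined}\n"
            )


def run_pipeline(config: dict | None, out_dir) -> dict:
    """Execute the stages in order; returns the manifest dict.

    Outputs per stage are written before the next stage starts; any
    failure aborts the run with a stage-tagged error.
    """
    cfg = resolve_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "config": cfg, "stages": {}}
    logging.getLogger("foldswitch").setLevel(cfg["log_level"])

    # -- stage: fold pair ---------------------------------------------------
    stage = "fold_pair"
    try:
        fp = cfg["fold_pair"]
        if fp.get("source", "synthetic") == "synthetic":
            spec = ToyFoldSpec(seed=int(cfg["seed"]), **{
                k: v for k, v in fp.get("synthetic", {}).items() if v is not None
            })
            long_t, short_t, truth = make_fold_pair(spec)
            manifest["stages"][stage] = {
                "source": "synthetic", "planted_offset": truth.offset,
                "long_length": long_t.length, "short_length": short_t.length,
            }
        else:
            long_t = FoldTemplate.from_json(fp["long_json"])
            short_t = FoldTemplate.from_json(fp["short_json"])
            manifest["stages"][stage] = {
                "source": "files", "long_length": long_t.length, "short_length": short_t.length,
            }
        long_t.to_json(out / "long.json")
        short_t.to_json(out / "short.json")
    except Exception as exc:
        raise DomainError(f"[{stage}] {exc}") from exc

    # -- stage: embed -------------------------------------------------------
    stage = "embed"
    try:
        anchor = tuple(cfg["anchor"])
        embeddings = enumerate_embeddings(long_t, short_t, anchor)
        reports = []
        for emb in embeddings:
            design0 = merge_initial(emb, long_t, short_t)
            reports.append(score_conflicts(emb, long_t, short_t, design0.long_sequence))
        ranked = rank_embeddings(reports)
        write_ranks_tsv(out / "ranks.tsv", ranked)
        manifest["stages"][stage] = {
            "n_embeddings": len(ranked),
            "best_offset": ranked[0].embedding.offset,
            "best_count": ranked[0].total_count,
        }
    except Exception as exc:
        raise DomainError(f"[{stage}] {exc}") from exc

    # -- stage: design ------------------------------------------------------
    stage = "design"
    try:
        dcfg = cfg["design"]
        model = EnergyModel.default()
        if dcfg.get("weights"):
            model = EnergyModel(
                contact=model.contact, burial=model.burial, ss=model.ss,
                weights=tuple(float(w) for w in dcfg["weights"]),
            )
        best = ranked[0]
        design = merge_initial(best.embedding, long_t, short_t)
        counts = {"merged": best.total_count}
        clusters = find_conflict_clusters(best, long_t)
        for cluster in clusters:
            design = resolve_cluster(
                design, cluster, long_t, short_t, model,
                candidate_alphabet=dcfg["candidate_alphabet"],
            )
        rep = score_conflicts(best.embedding, long_t, short_t, design.long_sequence)
        counts["after_clusters"] = rep.total_count
        if dcfg.get("run_nonoverlap", True):
            design = optimize_nonoverlap(
                design, long_t, short_t, model,
                candidate_alphabet=dcfg["candidate_alphabet"],
                max_sweeps=int(dcfg["max_sweeps"]),
            )
            rep = score_conflicts(best.embedding, long_t, short_t, design.long_sequence)
            counts["after_nonoverlap"] = rep.total_count

        for mut in cfg.get("variants") or []:
            pos, frm, to = int(mut[0]), str(mut[1]), str(mut[2])
            design, _ = apply_variant(design, [(pos, frm, to)])

        design_info = {
            "name": design.name,
            "long_sequence": design.long_sequence,
            "short_sequence": truncate_to_short(design),
            "mutation_log": [list(m) for m in design.mutation_log],
            "conflict_counts": counts,
            "energy_long": coarse_energy(design.long_sequence, long_t, model),
            "energy_short": coarse_energy(design.short_sequence, short_t, model),
        }
        with open(out / "design.json", "w") as fh:
            json.dump(design_info, fh, indent=1)
        write_fasta(
            out / "design.fasta",
            [
                (design.name + "_long", "long-fold construct", design.long_sequence),
                (design.name + "_short", "embedded short construct", design.short_sequence),
            ],
        )
        manifest["stages"][stage] = {
            "n_clusters": len(clusters),
            "n_mutations": len(design.mutation_log),
            "conflict_counts": counts,
        }
    except Exception as exc:
        raise DomainError(f"[{stage}] {exc}") from exc

    # -- stage: thermo linkage ---------------------------------------------
    stage = "thermo"
    tcfg = cfg["thermo"]
    if tcfg.get("dg_short") is not None and tcfg.get("dg_long") is not None:
        try:
            dg_switch = switch_free_energy(float(tcfg["dg_short"]), float(tcfg["dg_long"]))
            eq = three_state_populations(
                float(tcfg["dg_long"]), dg_switch, celsius_to_kelvin(float(tcfg["temperature_C"]))
            )
            pops = {
                "dG_switch_kcal_mol": dg_switch,
                "f_S": eq.f_S, "f_G": eq.f_G, "f_U": eq.f_U,
                "temperature_C": float(tcfg["temperature_C"]),
            }
            with open(out / "populations.json", "w") as fh:
                json.dump(pops, fh, indent=1)
            manifest["stages"][stage] = pops
        except Exception as exc:
            raise DomainError(f"[{stage}] {exc}") from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, ensure_ascii=False)
    return manifest
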