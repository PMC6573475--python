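"""Run configuration and end-to-end pipeline orchestration.

A single YAML config drives seeded runs of the full analysis flow
(synthetic data or external inputs -> diversity stats -> structure ->
ABC scenario comparison).  ``validate_config`` normalizes a config by
materializing every default explicitly and listing unknown keys instead of
ignoring them, so a normalized config is a fixed point of validation.
All tabular outputs are TSV and reports JSON; a manifest records the config
hash and every seed consumed, which makes two runs from the same config
value-identical.
"""

from __future__ import annotations

import copy
import hashlib
import json
import time
import warnings
from pathlib import Path

import numpy as np
import yaml

from . import abc as abc_mod
from . import coalescent, diversity, io as dio, structure, synth

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "out_dir": "msypop_run",
    "stages": ["synth", "stats", "structure", "abc"],
    "inputs": {
        "alignment": None,  # path; used instead of synth when given
        "alignment_format": "fasta",
        "metadata": None,
        "locus_length_bp": None,
    },
    "synth": {
        "n_populations": {"AA": 5, "TK": 5, "ST": 2},
        "block_ne": {"AA": 1500.0, "TK": 6000.0, "ST": 6000.0},
        "block_migration": {"AA": 1e-4, "TK": 2e-3, "ST": 2e-3},
        "samples_per_population": 15,
        "locus_length_bp": 50_000,
        "mutation_rate_per_bp_year": coalescent.DEFAULT_MU,
        "generation_time_years": coalescent.DEFAULT_GENERATION_TIME,
    },
    "stats": {
        "tajima_sims": 1000,
    },
    "structure": {
        "n_perm": 999,
        "mantel_perm": 999,
        "nmds_k": 2,
        "nmds_restarts": 20,
        "distance": "squared",
    },
    "abc": {
        "scenarios": ["demic", "cultural", "continuous_migration"],
        "t_target_years": 2000.0,
        "t_root_years": 4500.0,
        "generation_time_years": coalescent.DEFAULT_GENERATION_TIME,
        "mutation_rate_per_bp_year": coalescent.DEFAULT_MU,
        "locus_length_bp": coalescent.DEFAULT_LOCUS_LENGTH,
        "sample_sizes": {"AA": 10, "DAI": 10, "TARGET": 10},
        "size_priors": {
            "AA": [1e3, 1e5],
            "DAI": [1e3, 1e5],
            "TARGET": [1e3, 1e5],
        },
        "migration_prior": [1e-5, 1e-2],
        "n_sims_per_model": 500,
        "n_trees": 500,
        "observed": {
            "scenario": "demic",
            "ne": {"AA": 5e3, "DAI": 2e4, "TARGET": 1e4},
            "m": None,
        },
    },
}

KNOWN_STAGES = ("synth", "stats", "structure", "abc")


class ConfigError(ValueError):
    def __init__(self, errors: list[str]):
        super().__init__("; ".join(errors))
        self.errors = errors


def _merge(defaults: dict, user: dict, prefix: str, errors: list[str]) -> dict:
    out = copy.deepcopy(defaults)
    for key, val in user.items():
        if key not in defaults:
            errors.append(f"unknown key: {prefix}{key}")
            continue
        if isinstance(defaults[key], dict) and isinstance(val, dict):
            # leaf dicts (priors, sizes...) are replaced wholesale
            if defaults[key] and all(
                isinstance(v, dict) for v in defaults[key].values()
            ):
                out[key] = _merge(defaults[key], val, f"{prefix}{key}.", errors)
            elif key in ("inputs", "synth", "stats", "structure", "abc", "observed"):
                out[key] = _merge(defaults[key], val, f"{prefix}{key}.", errors)
            else:
                out[key] = copy.deepcopy(val)
        else:
            out[key] = copy.deepcopy(val)
    return out


def validate_config(source: str | Path | dict) -> dict:
    """Normalize a config file or dict, materializing all defaults.

    Raises :class:`ConfigError` listing every unknown key and invalid value.
    A returned config re-validates to itself (fixed point).
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            user = yaml.safe_load(fh) or {}
    else:
        user = copy.deepcopy(source)
    if not isinstance(user, dict):
        raise ConfigError(["config root must be a mapping"])
    errors: list[str] = []
    cfg = _merge(DEFAULT_CONFIG, user, "", errors)
    for st in cfg["stages"]:
        if st not in KNOWN_STAGES:
            errors.append(f"unknown stage: {st}")
    if cfg["abc"]["observed"]["scenario"] not in coalescent.SCENARIOS:
        errors.append(
            f"unknown observed scenario: {cfg['abc']['observed']['scenario']}"
        )
    for sc in cfg["abc"]["scenarios"]:
        if sc not in coalescent.SCENARIOS:
            errors.append(f"unknown abc scenario: {sc}")
    if errors:
        raise ConfigError(errors)
    return cfg


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=float).encode()
    ).hexdigest()[:16]


def _scenario_models(abc_cfg: dict) -> dict[str, coalescent.DemographicModel]:
    models = {}
    for sc in abc_cfg["scenarios"]:
        models[sc] = coalescent.DemographicModel(
            scenario=sc,
            t_target_years=abc_cfg["t_target_years"],
            t_root_years=abc_cfg["t_root_years"],
            generation_time_years=abc_cfg["generation_time_years"],
            size_priors={
                d: tuple(b) for d, b in abc_cfg["size_priors"].items()
            },
            migration_prior=(
                tuple(abc_cfg["migration_prior"])
                if sc == "continuous_migration"
                else None
            ),
            mutation_rate_per_bp_year=abc_cfg["mutation_rate_per_bp_year"],
            locus_length_bp=abc_cfg["locus_length_bp"],
            sample_sizes=dict(abc_cfg["sample_sizes"]),
        )
    return models


def run_pipeline(config: str | Path | dict, out_dir: str | Path | None = None) -> Path:
    """Execute the configured stages in dependency order.

    Writes all stage outputs, a ``manifest.json`` (config hash, seeds, stage
    timings) and a log to the output directory.  A stage failure leaves
    completed outputs intact and drops a ``FAILED`` marker before
    re-raising.
    """
    cfg = validate_config(config)
    out = Path(out_dir or cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    rng = np.random.default_rng(seed)
    stage_seeds = {st: int(rng.integers(2**31 - 1)) for st in KNOWN_STAGES}
    manifest: dict = {
        "config_hash": config_hash(cfg),
        "seed": seed,
        "stage_seeds": stage_seeds,
        "stages": list(cfg["stages"]),
        "timings_s": {},
    }
    log_lines: list[str] = [f"config_hash={manifest['config_hash']}"]

    alignment = None
    metadata = None
    summaries = None
    phist = None

    try:
        if cfg["inputs"]["alignment"]:
            path = Path(cfg["inputs"]["alignment"])
            if not path.exists():
                raise FileNotFoundError(path)
            alignment = dio.read_alignment(
                path,
                cfg["inputs"]["alignment_format"],
                cfg["inputs"]["locus_length_bp"],
            )
            if cfg["inputs"]["metadata"]:
                metadata = dio.read_metadata(cfg["inputs"]["metadata"])
            log_lines.append(f"loaded alignment from {path}")

        for stage in cfg["stages"]:
            t0 = time.perf_counter()
            if stage == "synth":
                if alignment is not None:
                    log_lines.append("synth skipped: external alignment supplied")
                    continue
                design = synth.StudyDesign(
                    seed=stage_seeds["synth"], **cfg["synth"]
                )
                alignment, metadata, truth = synth.generate_study(design)
                dio.write_alignment(alignment, out / "alignment.fasta")
                dio.write_metadata(metadata, out / "metadata.tsv")
                (out / "truth_manifest.json").write_text(
                    json.dumps(truth, indent=2, default=float)
                )
                log_lines.append(
                    f"synth: {alignment.n_samples} samples, "
                    f"{alignment.n_sites} sites, seed={stage_seeds['synth']}"
                )
            elif stage == "stats":
                if alignment is None:
                    raise ValueError("stats stage requires an alignment")
                summaries = diversity.population_summaries(
                    alignment,
                    metadata,
                    n_sims=cfg["stats"]["tajima_sims"],
                    seed=stage_seeds["stats"],
                )
                dio.write_table(
                    diversity.summaries_to_rows(summaries), out / "stats.tsv"
                )
                log_lines.append(
                    f"stats: {len(summaries)} populations, "
                    f"seed={stage_seeds['stats']}"
                )
            elif stage == "structure":
                if alignment is None:
                    raise ValueError("structure stage requires an alignment")
                scfg = cfg["structure"]
                sseed = stage_seeds["structure"]
                phist, pvals = structure.phist_pairwise(
                    alignment,
                    n_perm=scfg["n_perm"],
                    seed=sseed,
                    distance=scfg["distance"],
                )
                dio.write_matrix(phist, out / "phist.tsv")
                dio.write_matrix(pvals, out / "phist_pvalues.tsv")
                grouping = None
                if metadata:
                    grouping = {
                        m.code: m.language_family
                        for m in metadata
                        if m.code in phist.labels
                    }
                am_rows = []
                if grouping and len(set(grouping.values())) >= 2:
                    res = structure.amova(
                        alignment,
                        grouping,
                        n_perm=scfg["n_perm"],
                        seed=sseed + 1,
                        distance=scfg["distance"],
                    )
                    for comp in res.variance_components:
                        am_rows.append(
                            {
                                "component": comp,
                                "variance": res.variance_components[comp],
                                "percent": res.percentages[comp],
                            }
                        )
                    for phi, val in res.phi_stats.items():
                        am_rows.append(
                            {
                                "component": phi,
                                "variance": val,
                                "percent": res.p_values.get(phi, float("nan")),
                            }
                        )
                dio.write_table(am_rows, out / "amova.tsv")
                table = dio.collapse_haplotypes(alignment)
                dio.write_matrix(
                    structure.shared_haplotype_matrix(table, "per_pair"),
                    out / "shared_haplotypes.tsv",
                )
                if metadata:
                    geo_meta = [m for m in metadata if m.code in phist.labels]
                    geo = structure.geographic_distance_matrix(geo_meta)
                    # align label order with phist
                    order = [geo.labels.index(c) for c in phist.labels]
                    geo = dio.DistanceMatrix(
                        phist.labels,
                        geo.values[np.ix_(order, order)],
                        kind="geographic",
                    )
                    man = structure.mantel(
                        phist, geo, n_perm=scfg["mantel_perm"], seed=sseed + 2
                    )
                    dio.write_table(
                        [{"r": man.r, "p": man.p, "n_perm": man.n_permutations}],
                        out / "mantel.tsv",
                    )
                ords = structure.nmds(
                    phist,
                    k=scfg["nmds_k"],
                    n_restarts=scfg["nmds_restarts"],
                    seed=sseed + 3,
                )
                coord_rows = [
                    {
                        "population": lab,
                        **{
                            f"dim{d + 1}": ords.coordinates[i, d]
                            for d in range(scfg["nmds_k"])
                        },
                    }
                    for i, lab in enumerate(ords.labels)
                ]
                dio.write_table(coord_rows, out / "mds_coords.tsv")
                if metadata and summaries:
                    try:
                        rows = structure.residence_contrast_report(
                            summaries, phist, metadata
                        )
                        dio.write_table(rows, out / "contrasts.tsv")
                    except dio.DegenerateInputError as exc:
                        log_lines.append(f"contrasts skipped: {exc}")
                log_lines.append(f"structure: seed={sseed}")
            elif stage == "abc":
                acfg = cfg["abc"]
                aseed = stage_seeds["abc"]
                models = _scenario_models(acfg)
                obs_cfg = acfg["observed"]
                obs_model = models.get(obs_cfg["scenario"]) or (
                    coalescent.DemographicModel(
                        scenario=obs_cfg["scenario"],
                        t_target_years=acfg["t_target_years"],
                        t_root_years=acfg["t_root_years"],
                        generation_time_years=acfg["generation_time_years"],
                        size_priors={
                            d: tuple(b) for d, b in acfg["size_priors"].items()
                        },
                        mutation_rate_per_bp_year=acfg[
                            "mutation_rate_per_bp_year"
                        ],
                        locus_length_bp=acfg["locus_length_bp"],
                        sample_sizes=dict(acfg["sample_sizes"]),
                    )
                )
                truth = coalescent.ParameterDraw(
                    ne={k: float(v) for k, v in obs_cfg["ne"].items()},
                    m=obs_cfg["m"],
                )
                obs_aln, obs_sfs, obs_manifest = synth.generate_observed_for_abc(
                    obs_model, truth, seed=aseed
                )
                (out / "observed_manifest.json").write_text(
                    json.dumps(obs_manifest, indent=2, default=float)
                )
                table = abc_mod.build_reference_table(
                    models, acfg["n_sims_per_model"], base_seed=aseed + 1
                )
                table.to_tsv(out / "reference_table.tsv")
                report = abc_mod.run_model_comparison(
                    models,
                    obs_sfs.flatten(),
                    n_trees=acfg["n_trees"],
                    seed=aseed,
                    table=table,
                )
                (out / "abc_report.json").write_text(
                    json.dumps(report, indent=2, default=float)
                )
                log_lines.append(
                    f"abc: selected={report['selected_model']}, seed={aseed}"
                )
            manifest["timings_s"][stage] = round(time.perf_counter() - t0, 3)
    except Exception as exc:
        (out / "FAILED").write_text(f"{type(exc).__name__}: {exc}\n")
        (out / "run.log").write_text("\n".join(log_lines) + f"\nFAILED: {exc}\n")
        raise

    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True)
    )
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return out
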