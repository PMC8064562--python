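"""Stage orchestration: simulate -> distance -> delimit -> assign ->
popgen -> sdm, driven by one YAML config, with a JSON manifest.

Every stage writes its outputs under ``<outdir>/<stage>/``; the manifest
records the resolved configuration, the top-level seed, each stage's
parameters and the SHA-256 checksum of every file written, so a run is
fully reproducible from the manifest alone. All randomness flows from the
single top-level seed: stage k uses ``SeedSequence(seed, spawn_key=(k,))``,
so any stage can be re-run on its own with identical results.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .delimit import prior_sweep, recursive_delimit
from .distances import distance_matrix, nj_tree, write_newick
from .exceptions import PipelineError
from .io import (
    COMBINATIONS,
    load_synonym_groups,
    read_fasta,
    read_sample_table,
    write_fasta,
)
from .popgen import (
    amova_one_level,
    fst_permutation_test,
    haplotype_frequencies,
    nei_matrix,
)
from .sdm import (
    clean_occurrences,
    evaluate,
    extract_env,
    fit_maxent,
    jackknife_importance,
    predict_suitability,
    read_esri_ascii,
    sample_background,
    split_train_test,
    write_esri_ascii,
)
from .synth import (
    simulate_hit_table,
    simulate_landscape,
    simulate_study,
)
from .taxassign import (
    assign_all,
    consensus_assignment,
    read_hit_table,
    summarize_efficiency,
    write_hit_table,
)

STAGES = ("simulate", "distance", "delimit", "assign", "popgen", "sdm")

DEFAULT_CONFIG = Path(__file__).parent / "data" / "paper_like.yaml"


def load_config(path=None) -> dict:
    """Load and validate the run configuration (packaged default if None)."""
    path = Path(path) if path else DEFAULT_CONFIG
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    for section in STAGES:
        if section not in cfg:
            raise PipelineError(f"config missing section {section!r}")
    d = cfg["delimit"]
    if not (0 < d["P_min"] < d["P_max"]):
        raise PipelineError("delimit: need 0 < P_min < P_max")
    if cfg["sdm"]["test_fraction"] <= 0 or cfg["sdm"]["test_fraction"] >= 1:
        raise PipelineError("sdm: test_fraction must be in (0,1)")
    if cfg["popgen"]["n_perm"] < 1:
        raise PipelineError("popgen: n_perm must be >= 1")
    return cfg


def _stage_seed(seed: int, stage: str) -> np.random.SeedSequence:
    return np.random.SeedSequence(seed, spawn_key=(STAGES.index(stage),))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _require(path: Path, producer: str):
    if not path.exists():
        raise PipelineError(
            f"missing input {path}; run the {producer!r} stage first"
        )
    return path


def _markers(cfg) -> dict[str, int]:
    return dict(cfg["simulate"]["markers"])


def stage_simulate(cfg, outdir: Path, seed: int) -> list[Path]:
    sc = cfg["simulate"]
    ss = _stage_seed(seed, "simulate")
    sub = ss.spawn(3)
    stage_dir = outdir / "simulate"
    stage_dir.mkdir(parents=True, exist_ok=True)

    sites = read_sample_table().head(sc["n_sites"])
    records_by_marker, popmap, truth = simulate_study(
        sites,
        k_species=sc["k_species"],
        specimens_per_site=tuple(sc["specimens_per_site"]),
        markers=_markers(cfg),
        intra=sc["intra"],
        inter=sc["inter"],
        kappa=sc["kappa"],
        seed=sub[0],
    )
    written = []
    for marker, recs in records_by_marker.items():
        p = stage_dir / f"{marker}.fasta"
        write_fasta(recs, p)
        written.append(p)
    pop_path = stage_dir / "population_map.csv"
    pd.DataFrame(
        {"specimen_id": list(popmap), "population": list(popmap.values())}
    ).to_csv(pop_path, index=False)
    written.append(pop_path)
    truth_path = stage_dir / "species_truth.json"
    truth_path.write_text(
        json.dumps(
            {"assignment": truth.assignment,
             "params": {k: v for k, v in truth.params.items() if k != "seed"}},
            indent=2, sort_keys=True,
        )
    )
    written.append(truth_path)

    ht = sc["hit_table"]
    hit_seeds = np.random.SeedSequence(seed, spawn_key=(0, 1)).spawn(
        len(records_by_marker)
    )
    for (marker, _), hseed in zip(records_by_marker.items(), hit_seeds):
        hits = simulate_hit_table(
            truth,
            score_noise_sd=ht["score_noise_sd"],
            decoy_rate=ht["decoy_rate"],
            seed=hseed,
        )
        p = stage_dir / f"hits_{marker}.tsv"
        write_hit_table(hits, p)
        written.append(p)

    lc = sc["landscape"]
    coeffs = np.zeros(lc["n_vars"])
    coeffs[0] = lc["dominant_coeff"]
    grids, occurrences, _ = simulate_landscape(
        n_vars=lc["n_vars"],
        nrows=lc["nrows"],
        ncols=lc["ncols"],
        coeffs=coeffs,
        n_presence=lc["n_presence"],
        seed=sub[2],
    )
    env_dir = stage_dir / "env"
    env_dir.mkdir(exist_ok=True)
    for g in grids:
        p = env_dir / f"{g.name}.asc"
        write_esri_ascii(g, p)
        written.append(p)
    occ_path = stage_dir / "occurrences.csv"
    occurrences.to_csv(occ_path, index=False, float_format="%.10g")
    written.append(occ_path)
    return written


def stage_distance(cfg, outdir: Path, seed: int) -> list[Path]:
    stage_dir = outdir / "distance"
    stage_dir.mkdir(parents=True, exist_ok=True)
    model = cfg["distance"]["model"]
    written = []
    for marker in _markers(cfg):
        fasta = _require(outdir / "simulate" / f"{marker}.fasta", "simulate")
        records = read_fasta(fasta)
        dm = distance_matrix(records, model=model)
        p = stage_dir / f"{marker}_{model}.csv"
        dm.to_csv(p)
        written.append(p)
        tree_path = stage_dir / f"{marker}_nj.nwk"
        write_newick(nj_tree(dm), tree_path)
        written.append(tree_path)
    return written


def stage_delimit(cfg, outdir: Path, seed: int) -> list[Path]:
    from .distances import DistanceMatrix

    stage_dir = outdir / "delimit"
    stage_dir.mkdir(parents=True, exist_ok=True)
    dc = cfg["delimit"]
    model = cfg["distance"]["model"]
    written = []
    for marker in _markers(cfg):
        matrix_path = _require(
            outdir / "distance" / f"{marker}_{model}.csv", "distance"
        )
        dm = DistanceMatrix.from_csv(matrix_path, model=model)
        sweep = prior_sweep(
            dm, P_min=dc["P_min"], P_max=dc["P_max"], n_steps=dc["n_steps"],
            X=dc["X"], W=dc["W"],
        )
        p = stage_dir / f"{marker}_sweep.tsv"
        sweep.n_groups_by_prior().to_csv(p, sep="\t", index=False,
                                         float_format="%.6g")
        written.append(p)
        part = recursive_delimit(dm, dc["report_prior"], X=dc["X"], W=dc["W"])
        pp = stage_dir / f"{marker}_partition.tsv"
        part.to_frame().to_csv(pp, sep="\t", index=False, float_format="%.6g")
        written.append(pp)
    return written


def stage_assign(cfg, outdir: Path, seed: int) -> list[Path]:
    stage_dir = outdir / "assign"
    stage_dir.mkdir(parents=True, exist_ok=True)
    ac = cfg["assign"]
    synonyms = load_synonym_groups()
    written = []
    for method in ac["methods"]:
        per_marker = {}
        for marker in _markers(cfg):
            hits_path = _require(
                outdir / "simulate" / f"hits_{marker}.tsv", "simulate"
            )
            hits = read_hit_table(hits_path)
            assignments = assign_all(
                hits, method=method, synonym_groups=synonyms,
                deviation=ac["deviation"],
            )
            per_marker[marker] = assignments
            p = stage_dir / f"assignments_{marker}_{method}.tsv"
            pd.DataFrame(
                [
                    (a.query_id, a.rank, a.taxon, a.tier,
                     a.n_candidate_species)
                    for a in assignments
                ],
                columns=["query_id", "rank", "taxon", "tier",
                         "n_candidate_species"],
            ).to_csv(p, sep="\t", index=False)
            written.append(p)
        by_label = dict(per_marker)
        for combo, members in COMBINATIONS.items():
            if not set(members) <= set(per_marker):
                continue  # combination unavailable for this marker roster
            by_query = {}
            for m in members:
                for a in per_marker[m]:
                    by_query.setdefault(a.query_id, []).append(a)
            by_label[combo] = [
                consensus_assignment(v, q, combo)
                for q, v in sorted(by_query.items())
            ]
        eff = summarize_efficiency(by_label)
        p = stage_dir / f"efficiency_{method}.csv"
        eff.to_csv(p, index=False, float_format="%.4f")
        written.append(p)
    return written


def stage_popgen(cfg, outdir: Path, seed: int) -> list[Path]:
    from .distances import DistanceMatrix

    stage_dir = outdir / "popgen"
    stage_dir.mkdir(parents=True, exist_ok=True)
    pc = cfg["popgen"]
    model = cfg["distance"]["model"]
    pop_path = _require(outdir / "simulate" / "population_map.csv", "simulate")
    pops = dict(
        pd.read_csv(pop_path)[["specimen_id", "population"]].itertuples(
            index=False, name=None
        )
    )
    ss = _stage_seed(seed, "popgen")
    marker_seeds = ss.spawn(len(_markers(cfg)))
    written = []
    for marker, mseed in zip(_markers(cfg), marker_seeds):
        matrix_path = _require(
            outdir / "distance" / f"{marker}_{model}.csv", "distance"
        )
        dm = DistanceMatrix.from_csv(matrix_path, model=model)
        result = amova_one_level(dm, pops)
        result.p_value = fst_permutation_test(
            dm, pops, n_perm=pc["n_perm"], seed=mseed
        )
        result.n_permutations = pc["n_perm"]
        p = stage_dir / f"amova_{marker}.tsv"
        result.summary().to_csv(p, sep="\t", index=False, float_format="%.6g")
        written.append(p)
        fp = stage_dir / f"fst_{marker}.json"
        fp.write_text(
            json.dumps(
                {"fst": result.fst, "fst_raw": result.fst_raw,
                 "p_value": result.p_value,
                 "n_permutations": result.n_permutations},
                indent=2, sort_keys=True,
            )
        )
        written.append(fp)
        fasta = _require(outdir / "simulate" / f"{marker}.fasta", "simulate")
        records = read_fasta(fasta)
        by_pop: dict[str, list] = {}
        for r in records:
            by_pop.setdefault(pops[r.sample_id], []).append(r)
        freqs = haplotype_frequencies(by_pop)
        nm = nei_matrix(freqs)
        np_path = stage_dir / f"nei_{marker}.csv"
        nm.to_csv(np_path, float_format="%.6g")
        written.append(np_path)
    return written


def stage_sdm(cfg, outdir: Path, seed: int) -> list[Path]:
    stage_dir = outdir / "sdm"
    stage_dir.mkdir(parents=True, exist_ok=True)
    sc = cfg["sdm"]
    env_dir = _require(outdir / "simulate" / "env", "simulate")
    grid_paths = sorted(env_dir.glob("*.asc"))
    grids = [read_esri_ascii(p, name=p.stem) for p in grid_paths]
    occ_path = _require(outdir / "simulate" / "occurrences.csv", "simulate")
    occurrences = pd.read_csv(occ_path)

    matrix, extract_report = extract_env(occurrences, grids)
    cleaned, clean_report = clean_occurrences(
        matrix, min_flagged_vars=sc["min_flagged_vars"]
    )
    ss = _stage_seed(seed, "sdm")
    sub = ss.spawn(2)
    train_X, test_X = split_train_test(
        cleaned, test_fraction=sc["test_fraction"], seed=sub[0]
    )
    background_X, _ = sample_background(
        grids, n_background=sc["n_background"], seed=sub[1]
    )
    model = fit_maxent(train_X, background_X, beta=sc["beta"])
    written = []
    report_path = stage_dir / "cleaning_report.csv"
    clean_report.to_csv(report_path)
    written.append(report_path)
    for output in ("raw", "cumulative"):
        g = predict_suitability(model, grids, output=output)
        p = stage_dir / f"suitability_{output}.asc"
        write_esri_ascii(g, p)
        written.append(p)
    sdm_eval = evaluate(model, train_X, test_X, background_X,
                        test_fraction=sc["test_fraction"])
    eval_path = stage_dir / "evaluation.json"
    eval_path.write_text(json.dumps(sdm_eval.to_dict(), indent=2,
                                    sort_keys=True))
    written.append(eval_path)
    lam_path = stage_dir / "model_lambdas.csv"
    feature_names = [f"{v}_linear" for v in model.var_names] + [
        f"{v}_quadratic" for v in model.var_names
    ]
    pd.DataFrame({"feature": feature_names, "lambda": model.lambda_}).to_csv(
        lam_path, index=False, float_format="%.8g"
    )
    written.append(lam_path)
    if sc.get("jackknife", True):
        jk = jackknife_importance(train_X, test_X, background_X,
                                  beta=sc["beta"])
        jk_path = stage_dir / "jackknife.csv"
        jk.to_csv(jk_path, index=False, float_format="%.6g")
        written.append(jk_path)
    return written


_STAGE_FN = {
    "simulate": stage_simulate,
    "distance": stage_distance,
    "delimit": stage_delimit,
    "assign": stage_assign,
    "popgen": stage_popgen,
    "sdm": stage_sdm,
}


def run_stage(name: str, cfg: dict, outdir, seed: int = 0) -> list[Path]:
    """Run one named stage; returns the paths it wrote."""
    if name not in _STAGE_FN:
        raise PipelineError(f"unknown stage {name!r}; choose from {STAGES}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    return _STAGE_FN[name](cfg, outdir, seed)


def run_all(cfg: dict, outdir, seed: int = 0) -> Path:
    """Run every stage in order and write the manifest; returns its path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package_version": __version__,
        "seed": seed,
        "config": cfg,
        "stages": [],
    }
    for i, name in enumerate(STAGES):
        written = run_stage(name, cfg, outdir, seed=seed)
        manifest["stages"].append(
            {
                "name": name,
                "order": i,
                "params": cfg.get(name, {}),
                "seed_spawn_key": i,
                "outputs": {
                    str(p.relative_to(outdir)): _sha256(p) for p in sorted(written)
                },
            }
        )
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest_path
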