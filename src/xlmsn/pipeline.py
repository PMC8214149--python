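"""End-to-end orchestration: simulate -> digest -> search -> assemble ->
FDR -> collapse -> structural validation -> preference statistics.

The pipeline runs entirely on synthetic ground truth (or a user FASTA),
writes every stage table under the output directory, and returns a
summary dict whose counts equal the sums of the stage outputs.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .assemble import (
    ResidueLinkage,
    assemble as assemble_ids,
    collapse as collapse_ids,
    fdr_filter,
    ids_to_tsv,
    linkages_to_tsv,
    linkages_to_xinet_csv,
)
from .preference import (
    localization_precision,
    sites_from_linkage,
    weighted_occurrence,
)
from .structure import (
    compare_to_null,
    null_histogram,
    random_null,
    read_structure,
    satisfaction as satisfaction_rates,
    state_classify,
)
from .chem import get_linker
from .msn_io import read_mgf, write_mgf
from .search import Tolerances, search_spectra
from .seqdb import (
    DigestIndex,
    DigestParams,
    ProteinRecord,
    make_decoys,
    random_proteins,
    read_fasta,
    write_fasta,
)
from .simulate import (
    PlantedLinkage,
    SimConfig,
    TruthRecord,
    make_toy_structures,
    render_spectra,
    simulate_crosslinks,
    truth_to_tsv,
)

logger = logging.getLogger("xlmsn")

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    out_dir: str = "xlmsn_run"
    linker: str = "SDASO-M"
    seed: int = 0
    # database: either a FASTA path or synthetic-db parameters
    fasta: str | None = None
    n_proteins: int = 12
    protein_length: int = 320
    # simulation
    n_interlinks: int = 100
    n_deadend_nhs: int = 20
    n_deadend_diazirine: int = 20
    n_intralinks: int = 20
    ppm_sigma: float = 5.0
    noise_peaks: int = 20
    charges: tuple[int, ...] = (3, 4, 5)
    residue_preference: dict | None = None
    # digestion / search
    enzyme: str = "trypsin"
    max_missed: int | None = None
    precursor_ppm: float = 20.0
    ms3_window_da: float = 0.6
    min_score: float = 5.0
    var_mods: tuple[str, ...] = ()
    fdr_threshold: float = 0.01
    # structural validation (toy 4-model ensemble planted from results)
    validate_structures: bool = True
    n_models: int = 4
    null_cap: float = 100.0
    # stage toggles
    simulate: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "charges" in raw:
            raw["charges"] = tuple(raw["charges"])
        if "var_mods" in raw:
            raw["var_mods"] = tuple(raw["var_mods"])
        return cls(**raw)


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as e:
                raise RuntimeError(f"stage {name!r} failed: {e}") from e
            logger.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
            return out
        return wrapped
    return deco


def _plant_from_linkages(
    linkages: Sequence[ResidueLinkage],
    linker_threshold: float,
    n_models: int,
    rng: np.random.Generator,
    max_plants: int = 40,
) -> tuple[list[PlantedLinkage], dict[str, str]]:
    """Plant toy per-model distances for identified linkages.

    ~75% of planted linkages are satisfied in every model; the rest are
    satisfied only in a random proper subset, exercising state-specific
    classification.  Returns the plants and the accession -> chain map.
    """
    chain_letters = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    accs: list[str] = []
    for lk in linkages:
        for a in (lk.protein_a, lk.protein_b):
            if a not in accs:
                accs.append(a)
    if len(accs) > len(chain_letters):
        accs = accs[:len(chain_letters)]
    chain_map = {a: chain_letters[i] for i, a in enumerate(accs)}
    used: set[tuple[str, int]] = set()
    plants: list[PlantedLinkage] = []
    for lk in linkages:
        if len(plants) >= max_plants:
            break
        if lk.protein_a not in chain_map or lk.protein_b not in chain_map:
            continue
        ca, cb = chain_map[lk.protein_a], chain_map[lk.protein_b]
        ka, kb = (ca, lk.res_a), (cb, lk.res_b[0])
        if ka in used or kb in used or ka == kb:
            continue
        used.update((ka, kb))
        if rng.random() < 0.75:
            dists = tuple(float(rng.uniform(5.0, linker_threshold - 5.0))
                          for _ in range(n_models))
        else:
            size = int(rng.integers(1, n_models))
            sat = set(rng.choice(n_models, size=size, replace=False).tolist())
            dists = tuple(
                float(rng.uniform(5.0, linker_threshold - 5.0)) if m in sat
                else float(linker_threshold + rng.uniform(5.0, 30.0))
                for m in range(n_models))
        plants.append(PlantedLinkage(ca, lk.res_a, cb, lk.res_b[0], dists))
    return plants, chain_map


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full workflow; returns the summary dict (also written
    as ``summary.json`` in the output directory)."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    linker = get_linker(cfg.linker)
    tol = Tolerances(precursor_ppm=cfg.precursor_ppm,
                     pair_ppm=cfg.precursor_ppm,
                     ms3_window_da=cfg.ms3_window_da)
    digest_params = DigestParams(enzyme=cfg.enzyme, max_missed=cfg.max_missed)

    # --- database ---------------------------------------------------------
    if cfg.fasta is not None:
        if not Path(cfg.fasta).exists():
            raise FileNotFoundError(f"FASTA not found: {cfg.fasta}")
        targets = [r for r in read_fasta(cfg.fasta) if not r.is_decoy]
    else:
        targets = random_proteins(cfg.n_proteins, cfg.protein_length, cfg.seed)
    db = make_decoys(targets, seed=cfg.seed + 7)
    write_fasta(db, out / "db.fasta")

    # --- simulate ---------------------------------------------------------
    sim_kwargs = dict(
        linker=cfg.linker,
        n_interlinks=cfg.n_interlinks,
        n_deadend_nhs=cfg.n_deadend_nhs,
        n_deadend_diazirine=cfg.n_deadend_diazirine,
        n_intralinks=cfg.n_intralinks,
        charges=tuple(cfg.charges),
        ppm_sigma=cfg.ppm_sigma,
        noise_peaks=cfg.noise_peaks,
        seed=cfg.seed,
        digest=digest_params,
    )
    if cfg.residue_preference is not None:
        sim_kwargs["residue_preference"] = dict(cfg.residue_preference)
    sim_cfg = SimConfig(**sim_kwargs)
    truth = _stage("simulate")(simulate_crosslinks)(targets, sim_cfg)
    spectra = _stage("render")(render_spectra)(truth, sim_cfg)
    write_mgf(spectra, out / "spectra.mgf")
    truth_to_tsv(truth, out / "truth.tsv")

    # --- digest + search --------------------------------------------------
    index = _stage("digest")(DigestIndex)(db, digest_params)
    index.to_tsv(out / "digest.tsv")
    result = _stage("search")(search_spectra)(
        spectra, index, linker, tol,
        min_score=cfg.min_score, var_mods=cfg.var_mods)

    # --- assemble + FDR + collapse ---------------------------------------
    ids = _stage("assemble")(assemble_ids)(result, linker, tol)
    ids_to_tsv(ids, out / "crosslinks.tsv")
    kept, fdr_pct = _stage("fdr")(fdr_filter)(ids, cfg.fdr_threshold)
    ids_to_tsv(kept, out / "crosslinks_filtered.tsv")
    coll = _stage("collapse")(collapse_ids)(kept)
    linkages_to_tsv(coll.linkages, out / "linkages.tsv")
    linkages_to_xinet_csv(coll.linkages, out / "xinet.csv")

    # --- recovery against truth ------------------------------------------
    truth_interlinks = {
        (t.alpha.protein_ref.accession, t.alpha_protein_site,
         t.beta.protein_ref.accession, t.beta_protein_site)
        for t in truth if t.kind == "interlink"
    }
    recovered = set()
    for cid in kept:
        if cid.kind != "interlink":
            continue
        a_prot, a_res = cid.alpha.peptide.protein_ref.accession, \
            cid.alpha.peptide.protein_ref.start + cid.alpha.peptide.remnant.position - 1
        amb = cid.beta.ambiguity or (cid.beta.peptide.remnant.position,)
        for p in amb:
            b_res = cid.beta.peptide.protein_ref.start + p - 1
            key = (a_prot, a_res, cid.beta.peptide.protein_ref.accession, b_res)
            if key in truth_interlinks:
                recovered.add(key)
    recovery = (len(recovered) / len(truth_interlinks)
                if truth_interlinks else float("nan"))

    # --- preference -------------------------------------------------------
    interlink_ids = [c for c in kept if c.kind == "interlink"]
    amb_sets = []
    amb_sizes = []
    for c in interlink_ids:
        amb = c.beta.ambiguity or (c.beta.peptide.remnant.position,)
        amb_sets.append(sites_from_linkage(c.beta.peptide.sequence, amb))
        amb_sizes.append(len(amb))
    summary: dict = {}
    if amb_sets:
        px = _stage("preference")(weighted_occurrence)(amb_sets)
        px.to_csv(out / "preference.csv")
        summary["px_top_residue"] = str(px.index[0])
        summary["px_top_value"] = float(px["Px"].iloc[0])
        summary["px_E"] = float(px["Px"].get("E", 0.0))
        prec = localization_precision(amb_sizes)
        with open(out / "precision.json", "w") as fh:
            json.dump(prec, fh, indent=1)
        summary["localization_precision"] = {
            k: v for k, v in prec.items() if k != "empty"}

    # --- structural validation on a planted toy ensemble ------------------
    if cfg.validate_structures and coll.linkages:
        rng = np.random.default_rng(cfg.seed + 13)
        plants, chain_map = _plant_from_linkages(
            coll.linkages, linker.max_ca_ca, cfg.n_models, rng)
        if plants:
            st, planted = make_toy_structures(
                cfg.n_models, plants, seed=cfg.seed + 17)
            pdb_path = out / "toy_models.pdb"
            st.write_pdb(str(pdb_path))
            names = [f"s{i + 1}" for i in range(cfg.n_models)]
            models = read_structure(pdb_path, chain_map, names)
            planted_keys = {(p.chain_a, p.res_a, p.chain_b, p.res_b)
                            for p in plants}
            planted_lk = [
                lk for lk in coll.linkages
                if (chain_map.get(lk.protein_a), lk.res_a,
                    chain_map.get(lk.protein_b), lk.res_b[0]) in planted_keys
            ]
            rates, dres = _stage("validate")(
                satisfaction_rates)(planted_lk, models, linker)
            cats = state_classify(dres, names)
            obs = np.array([
                d for r in dres for d in r.distances.values() if d is not None])
            null = random_null(models[0], cfg.null_cap)
            ks_stat, ks_p = compare_to_null(obs, null)
            null_histogram(null).to_csv(
                out / "null_histogram.csv", index=False)
            import pandas as pd

            pd.DataFrame([
                {"linkage": f"{r.linkage.protein_a}:K{r.linkage.res_a}-"
                            f"{r.linkage.protein_b}:X{r.linkage.res_b_label}",
                 **{m: r.distances[m] for m in names},
                 "category": r.category or ""}
                for r in dres
            ]).to_csv(out / "distances.tsv", sep="\t", index=False)
            pd.Series(cats).to_csv(out / "state_counts.csv",
                                   header=["count"])
            summary["satisfaction_rates"] = {k: float(v)
                                             for k, v in rates.items()}
            summary["state_specific_total"] = int(sum(cats.values()))
            summary["ks_statistic"] = ks_stat
            summary["ks_pvalue"] = ks_p

    summary.update({
        "linker": cfg.linker,
        "seed": cfg.seed,
        "n_targets": len(targets),
        "n_db_entries": len(db),
        "n_truth": len(truth),
        "n_truth_interlinks": len(truth_interlinks),
        "n_spectra": len(spectra),
        "n_ids": len(ids),
        "n_ids_kept": len(kept),
        "n_interlinks_kept": len(interlink_ids),
        "n_deadends_kept": sum(c.kind == "deadend" for c in kept),
        "n_intralinks_kept": sum(c.kind == "intralink" for c in kept),
        "fdr_percent": fdr_pct,
        "interlink_recovery": recovery,
        "n_unique_sequences": coll.n_sequences,
        "n_unique_linkages": coll.n_linkages,
    })
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, default=str)
    return summary
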