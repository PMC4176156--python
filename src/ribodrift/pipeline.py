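"""Scenario presets, synthetic fixtures and the simulate→analyze suite.

The preset matrix mirrors the experimental design the package emulates:
drug concentrations are named by their fold of the reference dose
(100 μg/ml = "x1"), and "stress" is an acute drop of the initiation rate
shortly before drug addition plus a pool of initiation complexes queued at
the start codon — stress never touches elongation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import annotation_io, five_prime, metagene
from .annotation_io import FootprintAlignment, Transcript, TranscriptSet
from .simulator import (
    ArrestModel,
    K_UPTAKE_DEFAULT,
    SimulationScenario,
    UptakeModel,
    generate_library,
)

logger = logging.getLogger(__name__)

#: reference dose is 100 μg/ml; other doses are named by their fold of it
CONCENTRATION_PRESETS = {
    "x1/64": 100.0 / 64,
    "x1/16": 100.0 / 16,
    "x1/4": 100.0 / 4,
    "x1": 100.0,
    "x8": 800.0,
    "x100": 10000.0,
}


# ---------------------------------------------------------------------------
# scenario configuration
# ---------------------------------------------------------------------------


def scenario_from_dict(conf: dict) -> SimulationScenario:
    """Build a scenario from a flat key-value mapping (YAML/TOML style).

    Recognized keys: initiation_rate (number or [[t, rate], ...]),
    elongation_rate, queued_pool, queue_commit_rate, uorf_initiation_fraction,
    c_out, k_uptake, t_drug, k_i, t_harvest, t_burnin, exclusion_footprint,
    initiation_blocking, harvest_spread, ssu_start_fraction.  A missing or
    null ``c_out`` means a drug-free run.
    """
    conf = dict(conf)
    uptake = None
    if conf.get("c_out") is not None:
        uptake = UptakeModel(
            c_out=float(conf.pop("c_out")),
            t_drug=float(conf.pop("t_drug", conf.get("t_burnin", 6.0))),
            k_uptake=float(conf.pop("k_uptake", K_UPTAKE_DEFAULT)),
        )
    else:
        conf.pop("c_out", None)
        conf.pop("t_drug", None)
        conf.pop("k_uptake", None)
    arrest = ArrestModel(k_i=float(conf.pop("k_i", 5.0)))
    init = conf.pop("initiation_rate", 6.0)
    if isinstance(init, (list, tuple)):
        init = tuple((float(t), float(r)) for t, r in init)
    known = {
        "elongation_rate",
        "queued_pool",
        "queue_commit_rate",
        "uorf_initiation_fraction",
        "t_harvest",
        "t_burnin",
        "exclusion_footprint",
        "initiation_blocking",
        "harvest_spread",
        "ssu_start_fraction",
    }
    unknown = set(conf) - known
    if unknown:
        raise ValueError(f"unknown scenario keys: {sorted(unknown)}")
    return SimulationScenario(
        initiation_rate=init, uptake=uptake, arrest=arrest, **conf
    )


def load_scenario(path: str | Path) -> SimulationScenario:
    with open(path) as fh:
        conf = yaml.safe_load(fh) or {}
    return scenario_from_dict(conf)


def preset_scenario(
    concentration: str | None,
    stress: bool = False,
    t_burnin: float = 6.0,
    initiation_rate: float = 6.0,
    queued_pool_stress: int = 10,
    **overrides,
) -> SimulationScenario:
    """One cell of the concentration × stress preset matrix.

    ``concentration`` is a fold label ("x1/16", "x1", ...) or None for a
    drug-free run.  The stress preset drops the initiation rate fourfold
    2 min before drug addition and queues ``queued_pool_stress`` initiation
    complexes at the start codon — an acute initiation-side perturbation.
    """
    uptake = None
    if concentration is not None:
        uptake = UptakeModel(
            c_out=CONCENTRATION_PRESETS[concentration], t_drug=t_burnin
        )
    init: float | tuple = initiation_rate
    queued = 0
    if stress:
        t_stress = max(0.0, t_burnin - 2.0)
        init = ((0.0, initiation_rate), (t_stress, initiation_rate / 4.0))
        queued = queued_pool_stress
    return SimulationScenario(
        initiation_rate=init,
        queued_pool=queued,
        uptake=uptake,
        t_burnin=t_burnin,
        **overrides,
    )


# ---------------------------------------------------------------------------
# synthetic fixtures
# ---------------------------------------------------------------------------


def make_fixture(
    n_genes: int,
    seed: int,
    out_annotation: str | Path | None = None,
    out_alignments: str | Path | None = None,
    length_range: tuple[int, int] = (500, 3000),
    utr_range: tuple[int, int] = (50, 150),
    exon_count_choices: tuple[int, ...] = (1, 1, 1, 2, 3),
    uorf_fraction: float = 0.3,
    expression_range: tuple[float, float] = (1.0, 100.0),
    n_reads: int = 50_000,
) -> tuple[TranscriptSet, list[FootprintAlignment]]:
    """Generate a valid annotation plus a small aligned library.

    Genes mix exon counts, keep 5'UTRs of at least ``utr_range[0]`` nt and a
    ``uorf_fraction`` of them carry one uORF.  Reads are placed uniformly
    within each transcript with per-gene depth log-uniform over
    ``expression_range`` (relative levels: the fixture spans a 100-fold
    expression range by default; absolute rpkm additionally depends on
    library size and gene number).  Files are written (BED12 / BED6) when
    paths are given.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = np.random.default_rng(seed)
    transcripts = []
    width = max(1, len(str(n_genes)))
    for i in range(n_genes):
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        utr5 = int(rng.integers(utr_range[0], min(utr_range[1], length // 3) + 1))
        utr3 = min(50, max(0, length - utr5 - 60))
        cds_len = length - utr5 - utr3
        cds_len -= cds_len % 3
        cds_start = utr5
        uorfs: tuple = ()
        if rng.random() < uorf_fraction and utr5 >= 30:
            u_len = int(rng.choice([9, 12, 15, 18]))
            u_len = min(u_len, 3 * ((utr5 - 6) // 3))
            if u_len >= 6:
                u_start = int(rng.integers(0, utr5 - u_len + 1))
                uorfs = ((u_start, u_start + u_len),)
        transcripts.append(
            Transcript(
                id=f"tx{str(i + 1).zfill(width)}",
                length=length,
                cds_start=cds_start,
                cds_end=cds_start + cds_len,
                exon_count=int(rng.choice(exon_count_choices)),
                uorfs=uorfs,
                strand_on_genome="+" if rng.random() < 0.5 else "-",
            )
        )
    txs = TranscriptSet(transcripts)

    # per-gene read counts from log-uniform relative expression
    lo, hi = expression_range
    targets = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_genes))
    weights = targets * np.array([t.length for t in transcripts], dtype=float)
    counts = rng.multinomial(n_reads, weights / weights.sum())
    reads: list[FootprintAlignment] = []
    for tx, n in zip(transcripts, counts):
        lens = rng.integers(27, 32, size=n)
        starts = rng.integers(0, np.maximum(1, tx.length - lens))
        for s, ln in zip(starts, lens):
            reads.append(FootprintAlignment(tx.id, int(s), int(s + ln)))
    perm = rng.permutation(len(reads))
    reads = [reads[i] for i in perm]

    if out_annotation is not None:
        annotation_io.write_annotation(txs, out_annotation, format="bed12")
    if out_alignments is not None:
        annotation_io.write_alignments(reads, out_alignments)
    return txs, reads


# ---------------------------------------------------------------------------
# scenario suite
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Configuration for one simulate→analyze suite run."""

    annotation: Path
    out_dir: Path
    seed: int = 0
    concentrations: tuple[str | None, ...] = (None, "x1/16", "x1", "x8", "x100")
    stress_levels: tuple[bool, ...] = (False, True)
    n_cells: int = 20
    rrna_fraction: float = 0.0
    coverage_mode: str = "full"
    min_len: int = 1000
    min_rpkm: float = 30.0
    scenario_overrides: dict = field(default_factory=dict)


def _cell_name(conc: str | None, stress: bool) -> str:
    base = "nodrug" if conc is None else conc.replace("/", "_")
    return f"{base}__{'stress' if stress else 'baseline'}"


def run_scenario_suite(config: RunConfig) -> list[Path]:
    """Run every scenario cell end-to-end and write TSVs plus a manifest.

    Each cell yields ``<name>.profile.tsv`` (metagene) and
    ``<name>.summary.tsv`` (5'UTR share, class shares); the manifest records
    seeds and parameters so the run is reproducible byte for byte.
    """
    annotation = Path(config.annotation)
    if not annotation.exists():
        raise FileNotFoundError(f"annotation not found: {annotation}")
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    txs = annotation_io.read_annotation(annotation)

    outputs: list[Path] = []
    manifest: dict = {
        "seed": config.seed,
        "annotation": str(annotation),
        "n_cells": config.n_cells,
        "cells": {},
    }
    root = np.random.SeedSequence(config.seed)
    cells = [
        (conc, stress)
        for conc in config.concentrations
        for stress in config.stress_levels
    ]
    children = root.spawn(len(cells))
    for (conc, stress), child in zip(cells, children):
        name = _cell_name(conc, stress)
        cell_seed = int(child.generate_state(1)[0] % (2**31))
        try:
            scenario = preset_scenario(
                conc, stress=stress, **config.scenario_overrides
            )
            library = generate_library(
                txs,
                scenario,
                n_cells=config.n_cells,
                rrna_fraction=config.rrna_fraction,
                seed=cell_seed,
            )
            expr = metagene.expression_table(txs, library)
            selected = metagene.select_genes(
                txs, expr, min_len=config.min_len, min_rpkm=config.min_rpkm
            )
            covs = metagene.coverage_map(txs, library, mode=config.coverage_mode)
            profile = metagene.metagene_profile(txs, selected, covs)
            summary = five_prime.occupancy_summary(txs, library)
        except Exception as exc:
            raise RuntimeError(f"scenario {name!r} failed: {exc}") from exc

        profile_path = out_dir / f"{name}.profile.tsv"
        profile.write_tsv(profile_path)
        summary_path = out_dir / f"{name}.summary.tsv"
        with open(summary_path, "w") as fh:
            fh.write("key\tvalue\n")
            fh.write(f"utr5_share\t{summary.utr5_share:.6g}\n")
            fh.write(f"peak_area\t{metagene.peak_area(profile):.6g}\n")
            fh.write(f"n_genes\t{profile.n_genes}\n")
            fh.write(f"n_reads\t{len(library)}\n")
            for cls, share in summary.class_shares.items():
                fh.write(f"class_share:{cls}\t{share:.6g}\n")
        outputs.extend([profile_path, summary_path])
        manifest["cells"][name] = {
            "seed": cell_seed,
            "concentration": conc,
            "stress": stress,
            "c_out": None if conc is None else CONCENTRATION_PRESETS[conc],
            "n_genes": profile.n_genes,
            "n_reads": len(library),
        }
        logger.info("suite cell %s: %d reads, %d genes", name, len(library), profile.n_genes)

    manifest_path = out_dir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    outputs.append(manifest_path)
    return outputs
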