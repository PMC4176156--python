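"""Stochastic simulation of translation under cycloheximide uptake.

The model behind the 5' run-on artifact:

* The drug enters the cell by passive diffusion.  With extracellular
  concentration ``c_out`` and first-order uptake constant ``k_uptake``, the
  intracellular concentration after drug addition at ``t_drug`` is
  ``c_in(t) = c_out * (1 - exp(-k_uptake * (t - t_drug)))``.  The default
  ``k_uptake = ln(20)/2`` per minute puts 95% equilibration at exactly 2 min.
* Inhibition is not a step function.  Each attempted elongation step arrests
  the ribosome permanently with probability ``c_in / (c_in + k_i)``
  (half-saturation ``k_i``, default 5 μg/ml), so early after drug addition
  ribosomes still run on for many codons, while at equilibrium arrest is
  near-immediate.
* Initiation itself is not inhibited by the drug.  Ribosomes keep loading at
  the start codon for the whole harvest window; a ribosome that arrests
  within the first 10 codons, and any queued initiation complex, permanently
  occludes the start site so later initiation attempts on that mRNA are lost
  (``initiation_blocking``).  Transiently elongating ribosomes do not block —
  a momentary delay is absorbed into the initiation rate — which keeps the
  drug-free process an exact Poisson pipeline.

Two samplers produce statistically identical snapshots:

* a vectorized counting-process sampler (the default): each ribosome's
  arrest time is drawn by inverting the cumulative arrest hazard
  ``Λ(t) = ∫ 60·v·p_arrest(c_in) dt`` and its codon position by a Poisson
  count with mean ``∫ 60·v·(1 - p_arrest) dt`` — an exact decomposition of
  the per-step arrest/advance competition;
* an explicit event-driven simulation, used when steric ribosome exclusion
  is switched on and kept as an independent cross-check of the first.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .annotation_io import FootprintAlignment, Transcript, TranscriptSet

#: calibrated so that c_in reaches 95% of c_out 2 minutes after drug addition
K_UPTAKE_DEFAULT = math.log(20.0) / 2.0

#: target code for a ribosome translating the main ORF (otherwise uORF index)
MAIN_CDS = -1

#: distance from a footprint's 5' end to the first nucleotide of the P-site codon
P_SITE_OFFSET = 12

#: codons occluded around the start site by a stalled/queued ribosome
START_OCCLUSION_CODONS = 10

#: reference lengths for contamination reads (yeast 18S / 25S rRNA, nt)
RRNA_REFERENCES = {"rRNA_18S": 1800, "rRNA_25S": 3396}


@dataclass(frozen=True)
class UptakeModel:
    """First-order passive diffusion of the drug into the cell."""

    c_out: float  # extracellular concentration, μg/ml
    t_drug: float  # drug addition time, min
    k_uptake: float = K_UPTAKE_DEFAULT  # 1/min

    def __post_init__(self) -> None:
        if self.c_out < 0:
            raise ValueError("c_out must be >= 0")
        if self.k_uptake <= 0:
            raise ValueError("k_uptake must be > 0")


@dataclass(frozen=True)
class ArrestModel:
    """Per-attempted-step arrest probability c/(c + k_i)."""

    k_i: float = 5.0  # half-saturation concentration, μg/ml

    def __post_init__(self) -> None:
        if self.k_i <= 0:
            raise ValueError("k_i must be > 0")


def intracellular_concentration(t, uptake: UptakeModel):
    """Drug concentration inside the cell at time ``t`` (min); vectorized."""
    t = np.asarray(t, dtype=float)
    dt = np.clip(t - uptake.t_drug, 0.0, None)
    c = uptake.c_out * (-np.expm1(-uptake.k_uptake * dt))
    return float(c) if c.ndim == 0 else c


def arrest_probability(c_in, arrest: ArrestModel):
    """Probability that one attempted elongation step arrests permanently."""
    c = np.asarray(c_in, dtype=float)
    if np.any(c < 0):
        raise ValueError("c_in must be >= 0")
    p = c / (c + arrest.k_i)
    return float(p) if p.ndim == 0 else p


@dataclass(frozen=True)
class RibosomeState:
    """Snapshot of one on-mRNA ribosome at harvest."""

    codon_position: int
    arrested: bool
    target: int = MAIN_CDS  # MAIN_CDS or uORF index
    t_init: float = 0.0  # initiation (or queue-commit) time, min


@dataclass(frozen=True)
class SimulationScenario:
    """Time schedule and kinetic parameters for one simulated condition.

    ``initiation_rate`` is either a constant (initiations/min per transcript)
    or a piecewise-constant schedule ``((t0, rate0), (t1, rate1), ...)`` with
    each rate applying from its time until the next breakpoint.

    Stress never touches elongation: it enters only through the initiation
    schedule and the queued pool ``queued_pool`` (ribosomes sitting at the
    start codon when the drug arrives, each committing to elongation after an
    exponential delay with rate ``queue_commit_rate``).
    """

    initiation_rate: float | tuple[tuple[float, float], ...] = 6.0  # /min
    elongation_rate: float = 6.0  # codons/s
    queued_pool: int = 0
    queue_commit_rate: float = 1.0  # 1/min
    uorf_initiation_fraction: float = 0.0
    uptake: UptakeModel | None = None
    arrest: ArrestModel = field(default_factory=ArrestModel)
    t_harvest: float | None = None  # min; default t_drug + 5 (or t_burnin)
    t_burnin: float = 6.0  # min of drug-free equilibration from t = 0
    exclusion_footprint: int = 0  # codons; 0 = independent ribosomes
    initiation_blocking: bool = True
    harvest_spread: float = 0.0  # min; per-cell harvest uniform in a window
    ssu_start_fraction: float = 0.0  # share of short start-proximal (40S-like) reads

    def __post_init__(self) -> None:
        if self.t_harvest is None:
            t = (self.uptake.t_drug + 5.0) if self.uptake else self.t_burnin
            object.__setattr__(self, "t_harvest", t)
        if not isinstance(self.initiation_rate, (int, float)):
            sched = tuple((float(t), float(r)) for t, r in self.initiation_rate)
            if any(r < 0 for _, r in sched) or list(sched) != sorted(sched):
                raise ValueError("initiation schedule must be sorted with rates >= 0")
            object.__setattr__(self, "initiation_rate", sched)
        elif self.initiation_rate < 0:
            raise ValueError("initiation_rate must be >= 0")
        if self.elongation_rate < 0:
            raise ValueError("elongation_rate must be >= 0")
        if self.elongation_rate == 0 and self.max_initiation_rate > 0:
            raise ValueError(
                "zero elongation with nonzero initiation gives an unbounded queue"
            )
        if not 0.0 <= self.uorf_initiation_fraction <= 1.0:
            raise ValueError("uorf_initiation_fraction must be in [0,1]")
        if self.queued_pool < 0 or self.queue_commit_rate < 0:
            raise ValueError("queued pool parameters must be >= 0")
        if self.uptake is not None and self.t_harvest < self.uptake.t_drug:
            raise ValueError("t_harvest must be >= t_drug")
        if not 0.0 <= self.ssu_start_fraction < 1.0:
            raise ValueError("ssu_start_fraction must be in [0,1)")

    @property
    def max_initiation_rate(self) -> float:
        if isinstance(self.initiation_rate, tuple):
            return max(r for _, r in self.initiation_rate)
        return float(self.initiation_rate)

    def initiation_segments(self, t_end: float) -> list[tuple[float, float, float]]:
        """Piecewise-constant initiation rate as (t0, t1, rate) over [0, t_end]."""
        if isinstance(self.initiation_rate, tuple):
            points = list(self.initiation_rate)
            if not points or points[0][0] > 0:
                points.insert(0, (0.0, 0.0))  # silent before the first breakpoint
        else:
            points = [(0.0, float(self.initiation_rate))]
        segments = []
        for i, (t0, rate) in enumerate(points):
            t1 = points[i + 1][0] if i + 1 < len(points) else t_end
            t0, t1 = max(0.0, t0), min(t_end, t1)
            if t1 > t0:
                segments.append((t0, t1, rate))
        return segments

    def initiation_rate_at(self, t: float) -> float:
        rate = 0.0
        if isinstance(self.initiation_rate, tuple):
            for t0, r in self.initiation_rate:
                if t >= t0:
                    rate = r
        else:
            rate = float(self.initiation_rate)
        return rate


# ---------------------------------------------------------------------------
# hazard tables (shared across transcripts of one scenario)
# ---------------------------------------------------------------------------


class _KineticTables:
    """Cumulative arrest hazard and expected-advance tables on a time grid.

    With step-attempt rate r = 60*v per minute and per-attempt arrest
    probability p(t), arrests form an inhomogeneous Poisson process with rate
    r*p(t) and advances one with rate r*(1-p(t)).  The grid after drug
    addition is logarithmic so that the fast rise at very high doses is
    resolved as well as the slow rise at low ones.
    """

    def __init__(self, scenario: SimulationScenario, t_end: float):
        v = scenario.elongation_rate
        self.r = 60.0 * v  # attempted steps per minute
        uptake = scenario.uptake
        if uptake is None or uptake.c_out == 0.0 or t_end <= uptake.t_drug:
            self.t = np.array([0.0, max(t_end, 1e-9)])
            self.lam = np.zeros(2)
            self.adv = self.r * self.t
            return
        t_drug = uptake.t_drug
        post = t_end - t_drug
        grid_post = t_drug + np.concatenate(
            [[0.0], np.geomspace(min(1e-7, post / 10.0), post, 6000)]
        )
        pre = np.array([0.0]) if t_drug > 0 else np.empty(0)
        t = np.concatenate([pre, grid_post])
        p = arrest_probability(intracellular_concentration(t, uptake), scenario.arrest)
        dt = np.diff(t)
        lam_steps = 0.5 * (p[1:] + p[:-1]) * dt * self.r
        adv_steps = (dt - 0.5 * (p[1:] + p[:-1]) * dt) * self.r
        self.t = t
        self.lam = np.concatenate([[0.0], np.cumsum(lam_steps)])
        self.adv = np.concatenate([[0.0], np.cumsum(adv_steps)])

    def hazard_at(self, times: np.ndarray) -> np.ndarray:
        return np.interp(times, self.t, self.lam)

    def advance_at(self, times: np.ndarray) -> np.ndarray:
        return np.interp(times, self.t, self.adv)

    def invert_hazard(self, lam_values: np.ndarray) -> np.ndarray:
        """Earliest time with cumulative hazard >= lam_value (inf if never)."""
        out = np.interp(lam_values, self.lam, self.t, right=np.inf)
        return out


# ---------------------------------------------------------------------------
# vectorized counting-process sampler
# ---------------------------------------------------------------------------


def _orf_codons(tx: Transcript, target: int) -> int:
    if target == MAIN_CDS:
        return tx.cds_codons
    s, e = tx.uorfs[target]
    return (e - s) // 3


def _sample_states_vectorized(
    tx: Transcript,
    scenario: SimulationScenario,
    rng: np.random.Generator,
    n_cells: int,
    tables: _KineticTables | None = None,
) -> dict[str, np.ndarray]:
    """Harvest snapshot for ``n_cells`` independent cells, pooled.

    Returns arrays position / arrested / target / t_init over all on-mRNA
    ribosomes at harvest across the pooled cells.
    """
    t_h = float(scenario.t_harvest)
    if tables is None:
        tables = _KineticTables(scenario, t_h)
    uptake = scenario.uptake

    # per-cell harvest times (single snapshot by default)
    if scenario.harvest_spread > 0:
        harvest = t_h - scenario.harvest_spread * rng.random(n_cells)
    else:
        harvest = np.full(n_cells, t_h)

    # --- candidate walkers: Poisson initiations -------------------------
    t0_list, cell_list = [], []
    for a, b, rate in scenario.initiation_segments(t_h):
        n = rng.poisson(rate * (b - a) * n_cells)
        t0_list.append(a + (b - a) * rng.random(n))
        cell_list.append(rng.integers(0, n_cells, size=n))
    t0 = np.concatenate(t0_list) if t0_list else np.empty(0)
    cell = np.concatenate(cell_list) if cell_list else np.empty(0, dtype=int)
    order = np.argsort(t0, kind="stable")
    t0, cell = t0[order], cell[order]

    n_uorfs = len(tx.uorfs)
    target = np.full(t0.size, MAIN_CDS, dtype=int)
    if n_uorfs and scenario.uorf_initiation_fraction > 0:
        to_uorf = rng.random(t0.size) < scenario.uorf_initiation_fraction
        target[to_uorf] = rng.integers(0, n_uorfs, size=int(to_uorf.sum()))
    from_queue = np.zeros(t0.size, dtype=bool)

    # --- queued pool: commit to elongation after exponential delays ------
    if uptake is not None and scenario.queued_pool > 0:
        q = scenario.queued_pool * n_cells
        q_cell = np.repeat(np.arange(n_cells), scenario.queued_pool)
        if scenario.queue_commit_rate > 0:
            q_t0 = uptake.t_drug + rng.exponential(
                1.0 / scenario.queue_commit_rate, size=q
            )
        else:
            q_t0 = np.full(q, np.inf)
        t0 = np.concatenate([t0, q_t0])
        cell = np.concatenate([cell, q_cell])
        target = np.concatenate([target, np.full(q, MAIN_CDS, dtype=int)])
        from_queue = np.concatenate([from_queue, np.ones(q, dtype=bool)])

    if t0.size == 0:
        empty = np.empty(0)
        return dict(
            position=empty.astype(int),
            arrested=empty.astype(bool),
            target=empty.astype(int),
            t_init=empty,
        )

    harvest_w = harvest[cell]
    walks = t0 <= harvest_w  # queued ribosomes committing later stay at codon 0

    # --- walk each candidate: arrest time, then advance count -----------
    L = np.where(
        target == MAIN_CDS,
        tx.cds_codons,
        np.array(
            [(e - s) // 3 for s, e in tx.uorfs] or [0], dtype=int
        )[np.clip(target, 0, None)],
    )
    lam0 = tables.hazard_at(t0)
    t_arrest = tables.invert_hazard(lam0 + rng.exponential(size=t0.size))
    arrested = walks & (t_arrest <= harvest_w)
    t_stop = np.minimum(t_arrest, harvest_w)
    mu = np.where(walks, tables.advance_at(t_stop) - tables.advance_at(t0), 0.0)
    pos = rng.poisson(np.clip(mu, 0.0, None))
    terminated = walks & (pos >= L)
    arrested &= ~terminated
    pos = np.where(walks, pos, 0)

    # --- permanent occlusion of the start site --------------------------
    if scenario.initiation_blocking and uptake is not None:
        group = cell * (n_uorfs + 1) + np.where(target == MAIN_CDS, 0, target + 1)
        cap = np.full(n_cells * (n_uorfs + 1), np.inf)
        blockers = arrested & (pos < START_OCCLUSION_CODONS)
        np.minimum.at(cap, group[blockers], t_arrest[blockers])
        admitted = t0 < cap[group]
        # lost initiation attempts vanish; late-committing queued ribosomes
        # stay stacked at the start codon
        frozen = ~admitted & from_queue
        pos = np.where(frozen, 0, pos)
        arrested = np.where(frozen, False, arrested)
        terminated = np.where(frozen, False, terminated)
        keep = (admitted | from_queue) & ~terminated
    else:
        keep = ~terminated

    return dict(
        position=pos[keep].astype(int),
        arrested=arrested[keep],
        target=target[keep],
        t_init=t0[keep],
    )


# ---------------------------------------------------------------------------
# event-driven reference simulation
# ---------------------------------------------------------------------------


def _simulate_event_driven(
    tx: Transcript,
    scenario: SimulationScenario,
    rng: np.random.Generator,
    n_cells: int = 1,
) -> dict[str, np.ndarray]:
    """Explicit per-event simulation; supports steric ribosome exclusion."""
    t_h = float(scenario.t_harvest)
    uptake = scenario.uptake
    arrest = scenario.arrest
    step_rate = 60.0 * scenario.elongation_rate  # attempts per minute
    excl = scenario.exclusion_footprint

    out_pos, out_arr, out_tgt, out_init = [], [], [], []
    for _ in range(n_cells):
        events: list[tuple[float, int, str, int]] = []
        seq = 0

        def push(t: float, kind: str, payload: int) -> None:
            nonlocal seq
            heapq.heappush(events, (t, seq, kind, payload))
            seq += 1

        for a, b, rate in scenario.initiation_segments(t_h):
            n = rng.poisson(rate * (b - a))
            for t in np.sort(a + (b - a) * rng.random(n)):
                push(float(t), "init", 0)
        if uptake is not None and scenario.queued_pool > 0:
            for _ in range(scenario.queued_pool):
                if scenario.queue_commit_rate > 0:
                    tc = uptake.t_drug + rng.exponential(
                        1.0 / scenario.queue_commit_rate
                    )
                    push(float(tc), "commit", 0)
                else:
                    out_pos.append(0)
                    out_arr.append(False)
                    out_tgt.append(MAIN_CDS)
                    out_init.append(math.inf)

        ribosomes: dict[int, dict] = {}
        stacked: list[dict] = []  # queued ribosomes denied entry, stay at codon 0
        capped: set[int] = set()
        next_id = 0

        def blocked_by_exclusion(target: int, pos: int, rid: int) -> bool:
            if not excl:
                return False
            for other_id, r in ribosomes.items():
                if (
                    other_id != rid
                    and r["target"] == target
                    and pos <= r["pos"] < pos + excl
                ):
                    return True
            return False

        while events:
            t, _, kind, payload = heapq.heappop(events)
            if t > t_h:
                continue
            if kind in ("init", "commit"):
                target = MAIN_CDS
                if (
                    kind == "init"
                    and tx.uorfs
                    and rng.random() < scenario.uorf_initiation_fraction
                ):
                    target = int(rng.integers(0, len(tx.uorfs)))
                if scenario.initiation_blocking and target in capped:
                    if kind == "commit":
                        stacked.append(dict(pos=0, target=MAIN_CDS, t_init=t))
                    continue
                rid = next_id
                next_id += 1
                ribosomes[rid] = dict(
                    pos=0, target=target, t_init=t, arrested=False
                )
                if step_rate > 0:
                    push(t + rng.exponential(1.0 / step_rate), "step", rid)
            elif kind == "step":
                rib = ribosomes.get(payload)
                if rib is None or rib["arrested"]:
                    continue
                p = 0.0
                if uptake is not None:
                    p = arrest_probability(
                        intracellular_concentration(t, uptake), arrest
                    )
                if rng.random() < p:
                    rib["arrested"] = True
                    if rib["pos"] < START_OCCLUSION_CODONS:
                        capped.add(rib["target"])
                    continue
                if blocked_by_exclusion(rib["target"], rib["pos"] + 1, payload):
                    push(t + rng.exponential(1.0 / step_rate), "step", payload)
                    continue
                rib["pos"] += 1
                if rib["pos"] >= _orf_codons(tx, rib["target"]):
                    del ribosomes[payload]  # terminated, leaves the mRNA
                    continue
                push(t + rng.exponential(1.0 / step_rate), "step", payload)

        for rib in ribosomes.values():
            out_pos.append(rib["pos"])
            out_arr.append(bool(rib["arrested"]))
            out_tgt.append(rib["target"])
            out_init.append(rib["t_init"])
        for rib in stacked:
            out_pos.append(rib["pos"])
            out_arr.append(False)
            out_tgt.append(rib["target"])
            out_init.append(rib["t_init"])

    return dict(
        position=np.array(out_pos, dtype=int),
        arrested=np.array(out_arr, dtype=bool),
        target=np.array(out_tgt, dtype=int),
        t_init=np.array(out_init, dtype=float),
    )


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------


def simulate_transcript(
    tx: Transcript, scenario: SimulationScenario, seed: int
) -> list[RibosomeState]:
    """Positions of all on-mRNA ribosomes in one cell at harvest.

    Deterministic given ``seed``.  Uses the vectorized counting-process
    sampler unless steric exclusion is enabled, in which case the explicit
    event-driven simulation runs.
    """
    rng = np.random.default_rng(seed)
    if scenario.exclusion_footprint > 0:
        arrays = _simulate_event_driven(tx, scenario, rng, n_cells=1)
    else:
        arrays = _sample_states_vectorized(tx, scenario, rng, n_cells=1)
    states = [
        RibosomeState(
            codon_position=int(p),
            arrested=bool(a),
            target=int(g),
            t_init=float(t),
        )
        for p, a, g, t in zip(
            arrays["position"], arrays["arrested"], arrays["target"], arrays["t_init"]
        )
    ]
    states.sort(key=lambda s: (s.target, s.codon_position, s.t_init))
    return states


def footprints_from_states(
    tx: Transcript,
    states: list[RibosomeState],
    length_distribution: dict[int, float] | None = None,
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> list[FootprintAlignment]:
    """Turn ribosome positions into sequenced-footprint intervals.

    A ribosome with its P-site at codon ``j`` of an ORF starting at
    ``orf_start`` yields a footprint whose 5' end is ``orf_start + 3j - 12``;
    the length is drawn from ``length_distribution`` (default uniform on
    27..31 nt) and the interval is clipped to the transcript.  Clipped
    fragments shorter than 20 nt would not survive size selection and are
    dropped.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if length_distribution is None:
        length_distribution = {n: 1.0 for n in range(27, 32)}
    lengths = np.array(sorted(length_distribution), dtype=int)
    weights = np.array([length_distribution[n] for n in lengths], dtype=float)
    weights = weights / weights.sum()

    out = []
    if not states:
        return out
    drawn = rng.choice(lengths, size=len(states), p=weights)
    for state, read_len in zip(states, drawn):
        orf_start = (
            tx.cds_start if state.target == MAIN_CDS else tx.uorfs[state.target][0]
        )
        five = orf_start + 3 * state.codon_position - P_SITE_OFFSET
        start = max(0, five)
        end = min(tx.length, five + int(read_len))
        if end - start < 20:
            continue
        out.append(FootprintAlignment(tx.id, start, end, "footprint"))
    return out


def generate_library(
    txs: TranscriptSet,
    scenario: SimulationScenario,
    n_cells: int,
    rrna_fraction: float = 0.0,
    seed: int = 0,
    length_distribution: dict[int, float] | None = None,
    rrna_18s_share: float = 0.5,
) -> list[FootprintAlignment]:
    """Pooled footprint library over all transcripts and ``n_cells`` cells.

    rRNA-class contamination reads are appended so their expected share of
    the library equals ``rrna_fraction``, and the whole library is shuffled
    deterministically under ``seed``.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if not 0.0 <= rrna_fraction < 1.0:
        raise ValueError("rrna_fraction must be in [0,1)")

    ss = np.random.SeedSequence(seed)
    ids = txs.sorted_ids()
    children = ss.spawn(len(ids) + 2)
    tables = _KineticTables(scenario, float(scenario.t_harvest))

    reads: list[FootprintAlignment] = []
    for tid, child in zip(ids, children):
        tx = txs[tid]
        rng = np.random.default_rng(child)
        if scenario.exclusion_footprint > 0:
            arrays = _simulate_event_driven(tx, scenario, rng, n_cells=n_cells)
        else:
            arrays = _sample_states_vectorized(
                tx, scenario, rng, n_cells=n_cells, tables=tables
            )
        states = [
            RibosomeState(int(p), bool(a), int(g), float(t))
            for p, a, g, t in zip(
                arrays["position"],
                arrays["arrested"],
                arrays["target"],
                arrays["t_init"],
            )
        ]
        reads.extend(
            footprints_from_states(
                tx, states, length_distribution=length_distribution, rng=rng
            )
        )
        if scenario.ssu_start_fraction > 0 and states:
            # short start-proximal reads mimicking small-subunit footprints
            s = scenario.ssu_start_fraction
            n_ssu = int(round(s / (1.0 - s) * len(states)))
            for _ in range(n_ssu):
                read_len = int(rng.integers(25, 28))
                five = tx.cds_start - P_SITE_OFFSET + int(rng.integers(-3, 4))
                start = max(0, five)
                end = min(tx.length, five + read_len)
                if end - start >= 20:
                    reads.append(FootprintAlignment(tx.id, start, end, "footprint"))

    rng_tail = np.random.default_rng(children[-2])
    if rrna_fraction > 0 and reads:
        n_rrna = int(round(rrna_fraction / (1.0 - rrna_fraction) * len(reads)))
        refs = list(RRNA_REFERENCES)
        for _ in range(n_rrna):
            ref = refs[0] if rng_tail.random() < rrna_18s_share else refs[1]
            ref_len = RRNA_REFERENCES[ref]
            read_len = int(rng_tail.integers(27, 32))
            start = int(rng_tail.integers(0, ref_len - read_len))
            reads.append(FootprintAlignment(ref, start, start + read_len, ref))

    rng_shuffle = np.random.default_rng(children[-1])
    perm = rng_shuffle.permutation(len(reads))
    return [reads[i] for i in perm]
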