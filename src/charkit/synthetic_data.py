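"""Seeded generators for every input the analysis modules consume.

Each generator is a pure function of its seed and carries its ground
truth, so parameter-recovery, sensitivity/specificity and false-discovery
tests run with no external data:

* a compartment (susceptible / infected / resistant / phage) infection
  simulator producing OD killing curves over an MOI ladder,
* piecewise one-step growth titer curves (with an optional second burst)
  and exponential adsorption decay,
* genomes carrying a tail-assembly-chaperone-like ORF with a slippery
  motif and an in-phase -1 extension (plus motif-scrambled and
  premature-stop negatives, and an optional planted terminal repeat),
* strain x defense-system presence/absence tables with known odds ratios.

Noise is multiplicative lognormal throughout (positivity-preserving).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .enrichment import PresenceAbsenceTable
from .genome_io import STOP_CODONS, FeatureCoord, GenomeRecord, reverse_complement
from .kinetics import GrowthCurveSet, TiterSeries

NONSTOP_CODONS = tuple(sorted(
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in STOP_CODONS))

CELLS_PER_OD = 1e9  # cells/mL per OD unit, typical plate-reader calibration


@dataclass
class InfectionModelParams:
    """Parameters of the infection simulator (units in field comments).

    Defaults are anchored to the characterized phage: latent period 20 min,
    burst ~60 virions/cell, adsorption constant of order 1e-9 mL/cell/min.
    """

    r: float = 0.03              # bacterial growth rate, /min (~23 min doubling)
    K: float = 1.0               # carrying capacity, OD units
    k_ads: float = 5e-10         # adsorption rate, mL cell^-1 min^-1
    latent_min: float = 20.0     # minutes from infection to lysis
    burst: float = 60.0          # virions released per lysed cell
    resistant_frac: float = 0.0  # fraction of the inoculum never infected
    noise_sd: float = 0.0        # lognormal sigma of multiplicative noise
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.r, self.K, self.k_ads, self.latent_min) < 0:
            raise ValueError("rates and delays must be >= 0")
        if not (0 <= self.resistant_frac < 1):
            raise ValueError("resistant_frac must be in [0, 1)")
        if self.burst < 1:
            raise ValueError("burst must be >= 1")


def _lognoise(rng: np.random.Generator, sd: float, shape) -> np.ndarray:
    if sd <= 0:
        return np.ones(shape)
    return np.exp(rng.normal(0.0, sd, size=shape))


def simulate_growth_curves(params: InfectionModelParams,
                           mois: list[float],
                           times: np.ndarray,
                           b0_cells: float = 1e7,
                           dt: float = 0.5) -> GrowthCurveSet:
    """Forward-Euler integration of a delayed-lysis infection model.

    Susceptible cells B grow logistically toward K (shared with infected I
    and resistant R) and are adsorbed at rate k_ads*B*P; infected cells
    lyse latent_min later releasing ``burst`` phage each; the OD proxy is
    (B + I + R) / 1e9 cells per OD unit. All compartments stay
    non-negative (adsorption is capped at the susceptible pool per step).
    """
    times = np.asarray(times, dtype=float)
    dt = min(dt, 0.5)
    n_steps = int(math.ceil(times[-1] / dt)) + 1
    delay_steps = max(1, int(round(params.latent_min / dt)))
    k_cells = params.K * CELLS_PER_OD
    rng = np.random.default_rng(params.seed)

    def run(moi: float | None) -> np.ndarray:
        r0 = params.resistant_frac * b0_cells
        b = b0_cells - r0
        res = r0
        p = 0.0 if moi is None else moi * b0_cells
        lysis_queue = [0.0] * delay_steps  # infected cohorts by age
        infected = 0.0
        od = np.empty(n_steps)
        for step in range(n_steps):
            total = b + infected + res
            od[step] = total / CELLS_PER_OD
            logistic = 1.0 - total / k_cells
            growth_b = params.r * b * logistic * dt
            growth_r = params.r * res * logistic * dt
            new_inf = min(params.k_ads * b * p * dt, b)
            lysed = lysis_queue.pop(0)
            lysis_queue.append(new_inf)
            b = max(0.0, b + growth_b - new_inf)
            res = max(0.0, res + growth_r)
            infected = max(0.0, infected + new_inf - lysed)
            p = max(0.0, p - params.k_ads * b * p * dt + params.burst * lysed)
        idx = np.minimum((times / dt).round().astype(int), n_steps - 1)
        return od[idx]

    control = run(None) * _lognoise(rng, params.noise_sd, len(times))
    curves = {}
    for moi in mois:
        curves[float(moi)] = run(moi) * _lognoise(rng, params.noise_sd, len(times))
    return GrowthCurveSet(times=times, control_od=control, moi_curves=curves)


def simulate_one_step(params: InfectionModelParams,
                      times: np.ndarray,
                      n0: float = 1e4,
                      rise_min: float = 10.0,
                      second_burst: bool = False,
                      second_rise_min: float = 20.0,
                      second_gap_min: float = 20.0,
                      second_factor: float = 5.0
                      ) -> tuple[TiterSeries, dict]:
    """Piecewise one-step growth titer curve with known ground truth.

    Baseline n0 until the latent period, linear rise over ``rise_min`` to
    n0*burst, then plateau; optionally a second, slower rise (reduced
    growth, factor ``second_factor``) after ``second_gap_min`` of plateau.
    Returns (series, truth) with truth = {latent_min, burst, plateau_titer}.
    """
    times = np.asarray(times, dtype=float)
    plateau1 = n0 * params.burst
    t1 = params.latent_min
    t2 = t1 + rise_min
    y = np.empty_like(times)
    for i, t in enumerate(times):
        if t <= t1:
            y[i] = n0
        elif t < t2:
            y[i] = n0 + (plateau1 - n0) * (t - t1) / rise_min
        else:
            y[i] = plateau1
    if second_burst:
        t3 = t2 + second_gap_min
        t4 = t3 + second_rise_min
        plateau2 = plateau1 * second_factor
        for i, t in enumerate(times):
            if t3 < t < t4:
                y[i] = plateau1 + (plateau2 - plateau1) * (t - t3) / second_rise_min
            elif t >= t4:
                y[i] = plateau2
    rng = np.random.default_rng(params.seed)
    y = y * _lognoise(rng, params.noise_sd, len(times))
    series = TiterSeries(times=times, titer=y, n0=n0, volume_ml=1.0)
    truth = {"latent_min": params.latent_min, "burst": params.burst,
             "plateau_titer": plateau1}
    return series, truth


def simulate_adsorption(p0: float, k: float, cells: float,
                        times: np.ndarray, noise_sd: float = 0.0,
                        seed: int = 0) -> TiterSeries:
    """Exponential free-phage decay P(t) = p0 exp(-k * cells * t) with
    multiplicative lognormal noise on every reading except t = 0."""
    times = np.asarray(times, dtype=float)
    y = p0 * np.exp(-k * cells * times)
    rng = np.random.default_rng(seed)
    noise = _lognoise(rng, noise_sd, len(times))
    noise[times == 0] = 1.0  # P0 is the normalization point
    return TiterSeries(times=times, titer=y * noise, n0=p0)


# ----------------------------------------------------------- PRF genome maker

@dataclass
class PrfGenomeSpec:
    """Specification of a synthetic TAC-locus genome set.

    ``negatives`` maps genome index -> failure mode, one of
    ``"scramble_motif"`` (no slippery site in the 3' window) or
    ``"plant_minus1_stop"`` (a -1 frame stop codon 30 nt before the
    frame-0 stop). All other genomes are read-through positives.
    """

    n_genomes: int = 20
    locus_len: int = 240            # ORF length target, nt (rounded to codons)
    motif: str = "GTTTTT"
    extension_len: int = 300        # minimum -1 read-through past the stop, nt
    divergence: float = 0.0         # per-site substitution probability
    negatives: dict[int, str] = field(default_factory=dict)
    dtr_len: int = 0
    flank_len: int = 300
    minus_strand: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.extension_len <= 0:
            raise ValueError("extension_len must be positive")
        if not (0 <= self.divergence < 0.75):
            raise ValueError("divergence must be in [0, 0.75)")
        for idx, mode in self.negatives.items():
            if mode not in ("scramble_motif", "plant_minus1_stop"):
                raise ValueError(f"unknown negative mode {mode!r}")
            if not (0 <= idx < self.n_genomes):
                raise ValueError(f"negative index {idx} out of range")


def _random_codons(rng: np.random.Generator, n: int) -> list[str]:
    return [NONSTOP_CODONS[i] for i in rng.integers(0, len(NONSTOP_CODONS), n)]


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def _locus_ok(orf: str, downstream: str, motif: str, mode: str,
              motif_pos: int, planted_stop_rel: int, window: int = 60) -> bool:
    """Independent structural validation of a constructed/mutated locus.

    Checks frame-0 integrity, motif placement (exactly one in-window
    occurrence for positives, none for scrambled), and that the first -1
    frame stop after the slip is the planted one.
    """
    L = len(orf)
    if orf[-3:] not in STOP_CODONS:
        return False
    for i in range(0, L - 3, 3):
        if orf[i:i + 3] in STOP_CODONS:
            return False
    window_start = max(0, L - window)
    occ = []
    start = window_start
    while True:
        p = orf.find(motif, start)
        if p == -1:
            break
        occ.append(p)
        start = p + 1
    if mode == "scramble_motif":
        if occ:
            return False
        return True
    if occ != [motif_pos]:
        return False
    # -1 frame from the slip point through the planted stop
    seq = orf + downstream
    slip = motif_pos + len(motif) - 1
    for pos in range(slip, len(seq) - 2, 3):
        codon = seq[pos:pos + 3]
        if codon in STOP_CODONS:
            return pos == planted_stop_rel
    return False


def _build_ancestor(rng: np.random.Generator,
                    spec: PrfGenomeSpec) -> tuple[str, str, dict]:
    """Construct the ancestral positive locus (orf, downstream, truth).

    Layout (coding strand): ATG + body + GTTTTT + 30 nt spacer + TAA, with
    the -1 frame after the slip (last motif base) stop-free through the
    spacer and a downstream region, ending in a planted -1 TAA at least
    ``extension_len`` past the frame-0 stop. The motif is codon-aligned, so
    the -1 frame is never in phase with frame-0 stop codons. All genomes of
    a set (including the negatives, which are local edits of this locus)
    descend from this one ancestor, so divergence = 0 yields one allele.
    """
    motif = spec.motif.upper()
    n_codons = max(8, spec.locus_len // 3)
    n_spacer = 10  # 30 nt between motif end and stop codon

    for attempt in range(1000):
        body = _random_codons(rng, max(1, n_codons - n_spacer - 4))
        spacer = _random_codons(rng, n_spacer)
        orf = "ATG" + "".join(body) + motif + "".join(spacer) + "TAA"
        motif_pos = 3 + 3 * len(body)
        slip = motif_pos + len(motif) - 1
        L = len(orf)
        # exactly one in-window motif; no -1 stop between slip and the
        # frame-0 stop; frame-0 clean by construction of the codon sets
        if any(orf[p:p + 3] in STOP_CODONS
               for p in range(slip, L - 3, 3) if p + 3 <= L):
            continue
        window_start = max(0, L - 60)
        occ = [p for p in range(window_start, L - len(motif) + 1)
               if orf.startswith(motif, p)]
        if occ != [motif_pos]:
            continue
        break
    else:
        raise RuntimeError("could not build an ancestral locus for these "
                           "parameters; increase locus_len")

    # planted -1 stop: first -1 codon whose end reaches extension_len past
    # the frame-0 stop start
    min_stop = (L - 3) + spec.extension_len - 3
    k = math.ceil((min_stop - slip) / 3)
    planted_stop_rel = slip + 3 * k
    extension = (planted_stop_rel + 3) - (L - 3)

    first_full = slip + 3 * math.ceil((L - slip) / 3)
    downstream = _random_seq(rng, first_full - L)  # completes straddling codon
    pos = first_full
    while pos < planted_stop_rel:
        downstream += NONSTOP_CODONS[rng.integers(0, len(NONSTOP_CODONS))]
        pos += 3
    downstream += "TAA" + _random_seq(rng, 60)
    # the codon straddling the ORF boundary starts with the stop's last A,
    # so it can never be a stop; validate the whole construction anyway
    if not _locus_ok(orf, downstream, motif, "positive", motif_pos,
                     planted_stop_rel):
        raise RuntimeError("ancestral locus violated its own constraints")
    truth = {"motif_pos": motif_pos, "slip": slip,
             "planted_stop_rel": planted_stop_rel,
             "extension_nt": extension, "orf_len": L}
    return orf, downstream, truth


def _apply_mode(orf: str, truth: dict, motif: str, mode: str) -> tuple[str, dict]:
    """Derive a negative from the ancestral positive locus by a local edit."""
    t = dict(truth, mode=mode)
    if mode == "positive":
        return orf, t
    mp = truth["motif_pos"]
    if mode == "scramble_motif":
        orf = orf[:mp] + "GATCTT" + orf[mp + len(motif):]
        t["extension_nt"] = 0
        return orf, t
    # plant_minus1_stop: the -1 codon at the slip is motif[-1] + next two
    # bases; setting those bases to AA makes it read T|AA -> premature stop
    # 31 nt before the frame-0 stop (frame-0 codon becomes AA., not a stop)
    slip = truth["slip"]
    orf = orf[:slip + 1] + "AA" + orf[slip + 3:]
    t["planted_stop_rel"] = slip
    t["extension_nt"] = 0
    return orf, t


def _mutate_locus(rng: np.random.Generator, orf: str, downstream: str,
                  truth: dict, divergence: float, motif: str) -> tuple[str, str]:
    """Apply per-site substitutions that preserve the locus structure.

    Each proposed substitution is validated with the independent structural
    checker and reverted if it would break the frame-0 reading frame, the
    motif placement, or the planted -1 stop.
    """
    if divergence <= 0:
        return orf, downstream
    mode = truth["mode"]
    check_mode = "positive" if mode == "plant_minus1_stop" else mode
    L = len(orf)
    tail_start = truth["planted_stop_rel"] + 3 if mode != "plant_minus1_stop" \
        else len(orf) + len(downstream)
    seq = list(orf + downstream)
    protected = set(range(truth["motif_pos"], truth["motif_pos"] + len(motif)))
    protected |= {0, 1, 2}              # start codon
    protected |= {L - 3, L - 2, L - 1}  # frame-0 stop
    protected |= set(range(truth["planted_stop_rel"],
                           truth["planted_stop_rel"] + 3))  # planted -1 stop
    hits = rng.random(len(seq)) < divergence
    for pos in np.flatnonzero(hits):
        pos = int(pos)
        if pos in protected:
            continue
        old = seq[pos]
        choices = [b for b in "ACGT" if b != old]
        seq[pos] = choices[int(rng.integers(0, 3))]
        if pos >= tail_start:
            continue  # beyond the planted -1 stop: unconstrained
        new_orf = "".join(seq[:L])
        new_down = "".join(seq[L:])
        if not _locus_ok(new_orf, new_down, motif, check_mode,
                         truth["motif_pos"], truth["planted_stop_rel"]):
            seq[pos] = old
    return "".join(seq[:L]), "".join(seq[L:])


def make_prf_genomes(spec: PrfGenomeSpec) -> tuple[list[GenomeRecord], pd.DataFrame]:
    """Generate genomes carrying a TAC-like locus plus a per-genome truth table.

    Truth columns: genome_id, orf_id, mode, expect_site, expect_premature,
    expect_extension_nt, expect_pass, dtr_len.
    """
    rng = np.random.default_rng(spec.seed)
    genomes: list[GenomeRecord] = []
    rows = []
    dtr = _random_seq(rng, spec.dtr_len) if spec.dtr_len else ""
    anc_orf, anc_down, anc_truth = _build_ancestor(rng, spec)
    motif = spec.motif.upper()
    for i in range(spec.n_genomes):
        mode = spec.negatives.get(i, "positive")
        orf, truth = _apply_mode(anc_orf, anc_truth, motif, mode)
        orf, downstream = _mutate_locus(rng, orf, anc_down, truth,
                                        spec.divergence, motif)
        left = _random_seq(rng, spec.flank_len)
        right = _random_seq(rng, spec.flank_len)
        core = left + orf + downstream + right
        genome_seq = dtr + core + dtr
        orf_start = len(dtr) + len(left)
        orf_end = orf_start + len(orf)
        gid = f"synth_{i:03d}"
        orf_id = f"TAC_{i:03d}"
        if spec.minus_strand:
            genome_seq = reverse_complement(genome_seq)
            n = len(genome_seq)
            orf_start, orf_end = n - orf_end, n - orf_start
            strand = "-"
        else:
            strand = "+"
        feat = FeatureCoord(orf_id, orf_start, orf_end, strand, "CDS")
        genomes.append(GenomeRecord(id=gid, sequence=genome_seq,
                                    features=[feat], source="synthetic"))
        rows.append({
            "genome_id": gid,
            "orf_id": orf_id,
            "mode": mode,
            "expect_site": mode != "scramble_motif",
            "expect_premature": mode == "plant_minus1_stop",
            "expect_extension_nt": truth["extension_nt"] if mode == "positive" else 0,
            "expect_pass": mode == "positive",
            "dtr_len": spec.dtr_len,
        })
    return genomes, pd.DataFrame(rows)


# ---------------------------------------------------------- defense tables

def make_defense_table(n_strains: int, n_systems: int,
                       prevalence: float = 0.3,
                       enriched: dict[str, float] | None = None,
                       group_frac: float = 0.3,
                       seed: int = 0,
                       focal_label: str = "O11",
                       other_label: str = "non-O11") -> PresenceAbsenceTable:
    """Presence/absence table with group-enriched systems of known odds ratio.

    Group labels are Bernoulli(group_frac); each system is present with
    baseline probability ``prevalence``, shifted by ln(OR) on the log-odds
    scale in the focal group for systems named in ``enriched``.
    """
    if n_systems <= 0:
        raise ValueError("need at least one system")
    if n_strains <= 0:
        raise ValueError("need at least one strain")
    enriched = enriched or {}
    rng = np.random.default_rng(seed)
    systems = [f"sys_{j:02d}" for j in range(n_systems)]
    for name in enriched:
        if name not in systems:
            raise KeyError(f"enriched system {name!r} not among generated names")
    in_focal = rng.random(n_strains) < group_frac
    base_logit = math.log(prevalence / (1 - prevalence))
    matrix = np.zeros((n_strains, n_systems), dtype=bool)
    for j, name in enumerate(systems):
        shift = math.log(enriched[name]) if name in enriched else 0.0
        logit = base_logit + np.where(in_focal, shift, 0.0)
        prob = 1.0 / (1.0 + np.exp(-logit))
        matrix[:, j] = rng.random(n_strains) < prob
    return PresenceAbsenceTable(
        strain_ids=[f"strain_{i:03d}" for i in range(n_strains)],
        group=[focal_label if f else other_label for f in in_focal],
        systems=systems,
        matrix=matrix,
    )
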