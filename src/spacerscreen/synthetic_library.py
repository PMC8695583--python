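"""Mechanistic generator for synthetic sigma70 promoter-spacer screens.

The generator emulates the experimental system end to end: a Golden Gate
spacer library (random 12-23 bp spacers behind consensus -35/-10 hexamers),
toxicity-driven selection against the strongest clones, plate-reader time
courses of an mVenus reporter under gyrase inhibition (novobiocin), mirrored
treated/untreated endpoint screens, dose gradients, and EMSA titrations.

Model sketch
------------
* true promoter strength:  base_curve[L] x lognormal sequence effect x
  TG-motif damping (each TG dinucleotide damps multiplicatively; a tandem
  TG-TG at the extended -10 position damps further).
* supercoiling response:  each clone has an intrinsic superhelical-density
  optimum sigma_opt, linear in spacer GC content (GC-rich -> more negative
  optimum); instantaneous activity is a Gaussian in sigma around it.
* cellular supercoiling:  sigma relaxes from sigma_exp to sigma_stat as the
  culture leaves exponential phase; novobiocin shifts sigma toward
  relaxation by a growth-phase-dependent, dose-linear increment.
* strength-sensitivity coupling:  gyrase inhibition limits removal of
  positive supercoils downstream of the elongating polymerase, damping
  strong promoters under treatment; modeled as a power law in strength so
  the bias is linear in log-strength (the space in which the screen
  pipeline removes it).
* readout:  rfu(t) = cumulative per-cell production x OD(t) + blank + noise.

All randomness flows from one integer seed through named substreams.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .emsa_binding import BindingSeries
from .sequence_features import (
    SpacerSeq,
    MINUS10_CONSENSUS,
    MINUS35_CONSENSUS,
    extended_minus10,
    gc_content,
)

__all__ = [
    "SimConfig",
    "StrengthParams",
    "SelectionParams",
    "SupercoilingParams",
    "GrowthParams",
    "NoiseParams",
    "Clone",
    "PlateSeries",
    "OligoDesign",
    "BsaIInsert",
    "substream",
    "generate_library",
    "assign_strength",
    "apply_selection",
    "assign_supercoiling_params",
    "pick_colonies",
    "time_grid",
    "od_curve",
    "sigma_trajectory",
    "simulate_timecourse",
    "simulate_screen_pair",
    "simulate_dose_gradient",
    "simulate_emsa",
    "design_oligos",
    "simulate_bsai",
    "make_promoter_table",
    "make_gene_counts",
]

BASES = np.array(list("ACGT"))

#: default mean strength per spacer length, arbitrary units; peaked at 17 bp,
#: 16/18 bp close behind, moderate 19-23 bp plateau, steep drop below 15 bp.
DEFAULT_BASE_CURVE: dict[int, float] = {
    12: 80.0,
    13: 120.0,
    14: 200.0,
    15: 600.0,
    16: 870.0,
    17: 1000.0,
    18: 900.0,
    19: 700.0,
    20: 350.0,
    21: 300.0,
    22: 260.0,
    23: 240.0,
}


@dataclass(frozen=True)
class StrengthParams:
    """Sequence-to-strength model.

    sigma_log is the lognormal spread of the sequence effect, sized so the
    strongest/weakest of ~96 clones of one length differ ~10-fold.
    tg_damp multiplies strength once per TG dinucleotide; tandem_damp is an
    extra factor applied when a tandem TG-TG ends at the extended -10.
    """

    peak_length: int = 17
    base_curve: dict[int, float] = field(default_factory=lambda: dict(DEFAULT_BASE_CURVE))
    sigma_log: float = 0.46
    tg_damp: float = 0.60
    tandem_damp: float = 0.45
    background: float = 3.0

    def __post_init__(self) -> None:
        if not (0 < self.tg_damp <= 1 and 0 < self.tandem_damp <= 1):
            raise ValueError("damping multipliers must lie in (0, 1]")
        if max(self.base_curve, key=self.base_curve.get) != self.peak_length:
            raise ValueError("base_curve must be maximal at peak_length")


@dataclass(frozen=True)
class SelectionParams:
    """Phenomenological toxicity cull: clones above tox_threshold die w.p. p_kill."""

    tox_threshold: float = 600.0
    p_kill: float = 0.9

    def __post_init__(self) -> None:
        if not 0 <= self.p_kill <= 1:
            raise ValueError("p_kill must lie in [0, 1]")


@dataclass(frozen=True)
class SupercoilingParams:
    """Superhelical-density model.

    sigma_exp/sigma_stat are the cellular sigma in exponential and
    stationary phase (gap 0.025).  dsigma_treat_exp/stat are the relaxation
    shifts produced by 17 ug/mL novobiocin in the two phases (anchored at
    the measured 0.00195 / 0.00156); intermediate doses scale linearly.
    A clone's optimum is sigma_ref + opt_slope*(GC-0.5) + jitter, and its
    instantaneous activity a Gaussian of width ``width`` around it.
    elong_penalty couples strength to treatment via a power law in
    (1 + S/strength_ref).
    """

    sigma_exp: float = -0.060
    sigma_stat: float = -0.035
    dsigma_treat_exp: float = 0.00195
    dsigma_treat_stat: float = 0.00156
    conc_ref: float = 17.0
    sigma_ref: float = -0.034
    opt_slope: float = -0.07
    jitter: float = 0.006
    width: float = 0.015
    elong_penalty: float = 0.04
    strength_ref: float = 1.0

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("width must be positive")
        if self.elong_penalty < 0:
            raise ValueError("elong_penalty must be >= 0")


@dataclass(frozen=True)
class GrowthParams:
    """Logistic growth: od(t) = K od0 e^{rt} / (K + od0 (e^{rt} - 1))."""

    od0: float = 0.012
    K: float = 1.2
    r: float = 0.9  # 1/h
    t_end: float = 15.0  # h
    dt: float = 0.25  # h


@dataclass(frozen=True)
class NoiseParams:
    """Measurement noise and dedicated blank wells (medium only)."""

    od_sd: float = 0.003
    rfu_sd: float = 15.0
    blank_od: float = 0.04
    blank_rfu: float = 50.0


@dataclass(frozen=True)
class SimConfig:
    """Full study design: 12 spacer lengths x 96 picked colonies each."""

    lengths: tuple[int, ...] = tuple(range(12, 24))
    n_per_length: int = 96
    n_controls: int = 96
    seed: int = 0
    strength: StrengthParams = field(default_factory=StrengthParams)
    selection: SelectionParams = field(default_factory=SelectionParams)
    supercoiling: SupercoilingParams = field(default_factory=SupercoilingParams)
    growth: GrowthParams = field(default_factory=GrowthParams)
    noise: NoiseParams = field(default_factory=NoiseParams)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["lengths"] = list(self.lengths)
        d["strength"]["base_curve"] = {str(k): v for k, v in self.strength.base_curve.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        blocks = {
            "strength": StrengthParams,
            "selection": SelectionParams,
            "supercoiling": SupercoilingParams,
            "growth": GrowthParams,
            "noise": NoiseParams,
        }
        for key, klass in blocks.items():
            if key in d and isinstance(d[key], dict):
                block = dict(d[key])
                if key == "strength" and "base_curve" in block:
                    block["base_curve"] = {int(k): float(v) for k, v in block["base_curve"].items()}
                d[key] = klass(**block)
        if "lengths" in d:
            d["lengths"] = tuple(int(x) for x in d["lengths"])
        return cls(**d)


@dataclass
class Clone:
    """One library member: a picked colony carrying a unique spacer."""

    id: str
    spacer: SpacerSeq
    true_strength: float = float("nan")
    sigma_opt: float = float("nan")
    is_control: bool = False


@dataclass(frozen=True)
class PlateSeries:
    """Time-resolved OD600/RFU of one well under one condition (ug/mL)."""

    clone_id: str
    condition: float
    replicate: int
    time: np.ndarray
    od600: np.ndarray
    rfu: np.ndarray
    blank_od: float
    blank_rfu: float

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        od = np.asarray(self.od600, dtype=float)
        rfu = np.asarray(self.rfu, dtype=float)
        if not (t.size == od.size == rfu.size):
            raise ValueError("time, od600 and rfu must have equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("time grid must be strictly increasing")
        if np.any(od < 0):
            raise ValueError("od600 must be non-negative")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "od600", od)
        object.__setattr__(self, "rfu", rfu)


def substream(seed: int, name: str) -> np.random.Generator:
    """Independent generator for a named module substream of one root seed."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), zlib.crc32(name.encode())]))


# ---------------------------------------------------------------------------
# library construction


def _random_spacer(rng: np.random.Generator, length: int) -> SpacerSeq:
    return SpacerSeq("".join(rng.choice(BASES, size=length)))


def generate_library(cfg: SimConfig, rng: np.random.Generator | None = None) -> list[Clone]:
    """Draw n_per_length i.i.d. uniform-ACGT spacers for every length.

    Deterministic given the config seed.  Controls (promoter region replaced
    by random sequence) are appended with is_control=True.
    """
    rng = rng or substream(cfg.seed, "library")
    clones = [
        Clone(id=f"L{length}_{i:03d}", spacer=_random_spacer(rng, length))
        for length in cfg.lengths
        for i in range(cfg.n_per_length)
    ]
    clones += [
        Clone(
            id=f"ctrl_{i:03d}",
            spacer=_random_spacer(rng, 17),
            is_control=True,
        )
        for i in range(cfg.n_controls)
    ]
    return clones


def assign_strength(clone: Clone, cfg: SimConfig, rng: np.random.Generator) -> float:
    """True activity: length curve x lognormal sequence effect x TG damping."""
    st = cfg.strength
    if clone.is_control:
        clone.true_strength = st.background
        return clone.true_strength
    L = clone.spacer.length
    if L not in st.base_curve:
        raise ValueError(f"spacer length {L} outside configured lengths")
    report = extended_minus10(clone.spacer)
    s = st.base_curve[L] * float(np.exp(rng.normal(0.0, st.sigma_log)))
    s *= st.tg_damp**report.tg_count
    if report.tandem_len >= 2:
        s *= st.tandem_damp
    clone.true_strength = s
    return s


def apply_selection(
    clones: Sequence[Clone], cfg: SimConfig, rng: np.random.Generator
) -> tuple[list[Clone], pd.DataFrame]:
    """Toxicity cull: strength above tox_threshold dies with probability p_kill.

    Returns survivors (ids kept) and a per-length survival table.
    """
    sel = cfg.selection
    survivors: list[Clone] = []
    for clone in clones:
        doomed = (
            not clone.is_control
            and clone.true_strength > sel.tox_threshold
            and rng.random() < sel.p_kill
        )
        if not doomed:
            survivors.append(clone)
    rows = []
    for length in cfg.lengths:
        n0 = sum(1 for c in clones if not c.is_control and c.spacer.length == length)
        n1 = sum(1 for c in survivors if not c.is_control and c.spacer.length == length)
        rows.append({"length": length, "n_initial": n0, "n_survived": n1,
                     "survival": n1 / n0 if n0 else np.nan})
    return survivors, pd.DataFrame(rows)


def assign_supercoiling_params(clone: Clone, cfg: SimConfig, rng: np.random.Generator) -> float:
    """Clone's supercoiling optimum: linear in GC content plus jitter."""
    sc = cfg.supercoiling
    gc = gc_content(clone.spacer)
    clone.sigma_opt = sc.sigma_ref + sc.opt_slope * (gc - 0.5) + float(rng.normal(0.0, sc.jitter))
    return clone.sigma_opt


def pick_colonies(cfg: SimConfig, max_rounds: int = 60) -> list[Clone]:
    """Emulate picking n_per_length fresh colonies per length from library plates.

    Colonies on plates are already selection survivors, so batches of the
    random library are generated, parameterized and culled until every
    length has n_per_length survivors.  Controls are appended unculled.
    """
    rng_lib = substream(cfg.seed, "library")
    rng_str = substream(cfg.seed, "strength")
    rng_sel = substream(cfg.seed, "selection")
    rng_sc = substream(cfg.seed, "supercoiling")
    picked: dict[int, list[Clone]] = {L: [] for L in cfg.lengths}
    controls: list[Clone] = []
    for round_idx in range(max_rounds):
        batch = generate_library(cfg, rng_lib)
        for c in batch:
            c.id = f"r{round_idx}_{c.id}"
            assign_strength(c, cfg, rng_str)
            assign_supercoiling_params(c, cfg, rng_sc)
        survivors, _ = apply_selection([c for c in batch if not c.is_control], cfg, rng_sel)
        for c in survivors:
            slot = picked[c.spacer.length]
            if len(slot) < cfg.n_per_length:
                slot.append(c)
        if not controls:
            controls = [c for c in batch if c.is_control][: cfg.n_controls]
        if all(len(v) >= cfg.n_per_length for v in picked.values()):
            break
    else:
        raise RuntimeError("could not pick enough surviving colonies; selection too harsh")
    clones = [c for L in cfg.lengths for c in picked[L]] + controls
    return clones


# ---------------------------------------------------------------------------
# growth, supercoiling and reporter kinetics


def time_grid(cfg: SimConfig) -> np.ndarray:
    g = cfg.growth
    return np.arange(0.0, g.t_end + 1e-9, g.dt)


def od_curve(t: np.ndarray, cfg: SimConfig) -> np.ndarray:
    g = cfg.growth
    e = np.exp(g.r * np.asarray(t, dtype=float))
    return g.K * g.od0 * e / (g.K + g.od0 * (e - 1.0))


def sigma_trajectory(t: np.ndarray, condition: float, cfg: SimConfig) -> np.ndarray:
    """Cellular superhelical density over time under a novobiocin dose.

    sigma relaxes from sigma_exp to sigma_stat proportionally to the growth
    phase (od/K); treatment adds a dose-linear relaxation shift interpolated
    between the exponential- and stationary-phase anchors.
    """
    if condition < 0:
        raise ValueError("novobiocin concentration must be >= 0")
    sc = cfg.supercoiling
    phase = od_curve(t, cfg) / cfg.growth.K
    sigma = sc.sigma_exp + (sc.sigma_stat - sc.sigma_exp) * phase
    dsig = sc.dsigma_treat_exp + (sc.dsigma_treat_stat - sc.dsigma_treat_exp) * phase
    return sigma + dsig * (condition / sc.conc_ref)


def production_rates(
    strengths: np.ndarray,
    sigma_opts: np.ndarray,
    condition: float,
    cfg: SimConfig,
    t: np.ndarray,
) -> np.ndarray:
    """Per-cell reporter production, clones x timepoints.

    rate_i(t) = S_i * exp(-(sigma(t) - sigma_opt_i)^2 / (2 width^2))
                    * (1 + S_i/strength_ref)^(-elong_penalty * c / conc_ref)
    """
    sc = cfg.supercoiling
    sigma = sigma_trajectory(t, condition, cfg)[None, :]
    strengths = np.asarray(strengths, dtype=float)[:, None]
    sigma_opts = np.asarray(sigma_opts, dtype=float)[:, None]
    gauss = np.exp(-((sigma - sigma_opts) ** 2) / (2.0 * sc.width**2))
    coupling = np.exp(
        -sc.elong_penalty * np.log1p(strengths / sc.strength_ref) * (condition / sc.conc_ref)
    )
    return strengths * gauss * coupling


def _cumtrapz(y: np.ndarray, t: np.ndarray) -> np.ndarray:
    out = np.zeros_like(y)
    out[..., 1:] = np.cumsum((y[..., 1:] + y[..., :-1]) * 0.5 * np.diff(t), axis=-1)
    return out


def simulate_timecourse(
    clone: Clone,
    condition: float,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
    replicate: int = 0,
) -> PlateSeries:
    """Time-resolved OD600/RFU for one well.

    Measured OD includes the medium blank; RFU is cumulative per-cell
    production times OD plus blank and Gaussian read noise.
    """
    rng = rng or substream(cfg.seed, f"timecourse/{clone.id}/{condition}/{replicate}")
    t = time_grid(cfg)
    od = od_curve(t, cfg)
    rate = production_rates(
        np.array([clone.true_strength]), np.array([clone.sigma_opt]), condition, cfg, t
    )[0]
    cum = _cumtrapz(rate, t)
    nz = cfg.noise
    od_meas = np.clip(od + nz.blank_od + rng.normal(0.0, nz.od_sd, t.size), 0.0, None)
    rfu_meas = cum * od + nz.blank_rfu + rng.normal(0.0, nz.rfu_sd, t.size)
    return PlateSeries(
        clone_id=clone.id,
        condition=condition,
        replicate=replicate,
        time=t,
        od600=od_meas,
        rfu=rfu_meas,
        blank_od=nz.blank_od,
        blank_rfu=nz.blank_rfu,
    )


def _mirror_layout(clones: Sequence[Clone], cfg: SimConfig) -> tuple[list[str], list[str]]:
    """Mirrored-plate metadata: 8 clones of each length per 96-well plate."""
    plates, wells = [], []
    counters: dict[int, int] = {}
    length_col = {L: i + 1 for i, L in enumerate(cfg.lengths)}
    for c in clones:
        if c.is_control:
            j = counters.setdefault(-1, 0)
            counters[-1] += 1
            plates.append("PC")
            wells.append(f"{chr(ord('A') + j % 8)}{j // 8 + 1}")
        else:
            L = c.spacer.length
            j = counters.setdefault(L, 0)
            counters[L] += 1
            plates.append(f"P{j // 8 + 1:02d}")
            wells.append(f"{chr(ord('A') + j % 8)}{length_col.get(L, 12)}")
    return plates, wells


def _endpoint_frame(
    clones: Sequence[Clone], condition: float, cfg: SimConfig, rng: np.random.Generator
) -> pd.DataFrame:
    t = time_grid(cfg)
    od = od_curve(t, cfg)
    strengths = np.array([c.true_strength for c in clones])
    sig_opts = np.array([c.sigma_opt for c in clones])
    rate = production_rates(strengths, sig_opts, condition, cfg, t)
    cum_end = _cumtrapz(rate, t)[:, -1]
    nz = cfg.noise
    n = len(clones)
    od_meas = np.clip(od[-1] + nz.blank_od + rng.normal(0.0, nz.od_sd, n), 0.0, None)
    rfu_meas = cum_end * od[-1] + nz.blank_rfu + rng.normal(0.0, nz.rfu_sd, n)
    plates, wells = _mirror_layout(clones, cfg)
    return pd.DataFrame(
        {
            "clone_id": [c.id for c in clones],
            "length": [c.spacer.length for c in clones],
            "spacer": [c.spacer.seq for c in clones],
            "is_control": [c.is_control for c in clones],
            "plate": plates,
            "well": wells,
            "condition": condition,
            "od600": od_meas,
            "rfu": rfu_meas,
            "blank_od": nz.blank_od,
            "blank_rfu": nz.blank_rfu,
        }
    )


def simulate_screen_pair(
    clones: Sequence[Clone], cfg: SimConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Mirrored-plate endpoint screen: untreated vs 17 ug/mL novobiocin, 15 h."""
    rng = rng or substream(cfg.seed, "screen")
    frames = [
        _endpoint_frame(clones, 0.0, cfg, rng),
        _endpoint_frame(clones, cfg.supercoiling.conc_ref, cfg, rng),
    ]
    return pd.concat(frames, ignore_index=True)


def simulate_dose_gradient(
    clones: Sequence[Clone],
    cfg: SimConfig,
    concs: Iterable[float] = (0.0, 2.5, 5.0, 7.5, 10.0, 12.5, 15.0, 17.5),
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Endpoint screen across a novobiocin concentration gradient (ug/mL)."""
    rng = rng or substream(cfg.seed, "gradient")
    return pd.concat(
        [_endpoint_frame(clones, float(c), cfg, rng) for c in concs], ignore_index=True
    )


# ---------------------------------------------------------------------------
# EMSA titrations


def simulate_emsa(
    kd: float,
    n_hill: float,
    concs: Sequence[float],
    reps: int = 4,
    noise_sd: float = 0.02,
    seed: int = 0,
) -> BindingSeries:
    """Hill-model titration: theta = c^n/(kd^n + c^n) + Gaussian noise, clipped."""
    if kd <= 0:
        raise ValueError("kd must be positive (nM)")
    if n_hill <= 0:
        raise ValueError("Hill coefficient must be positive")
    conc = np.asarray(list(concs), dtype=float)
    if np.any(conc <= 0):
        raise ValueError("concentrations must be positive (nM)")
    rng = substream(seed, "emsa")
    theta = conc[None, :] ** n_hill / (kd**n_hill + conc[None, :] ** n_hill)
    theta = theta + rng.normal(0.0, noise_sd, size=(reps, conc.size))
    return BindingSeries(concentrations=conc, theta=np.clip(theta, 0.0, 1.0))


# ---------------------------------------------------------------------------
# Golden Gate oligo design

_TOP_PREFIX = "GGTCTCGGACA"
_TOP_SUFFIX = "TATACGAGACCGTGTCTATCAC"
_HELPER = "GTGATAGACACGGTCTCG"
_BSAI = "GGTCTC"
_BSAI_RC = "GAGACC"


@dataclass(frozen=True)
class OligoDesign:
    """Top/helper oligo pair for Golden Gate insertion of one spacer."""

    top_oligo: str
    helper_oligo: str
    overhang_left: str = "GACA"
    overhang_right: str = "TATA"


@dataclass(frozen=True)
class BsaIInsert:
    """Double-stranded insert released by BsaI: spacer with 4-nt 5' overhangs."""

    spacer: str
    overhang_left: str
    overhang_right: str


def design_oligos(spacer: "SpacerSeq | str") -> OligoDesign:
    """Design the annealing oligo pair for one spacer (BsaI Golden Gate scheme)."""
    s = spacer if isinstance(spacer, SpacerSeq) else SpacerSeq(str(spacer))
    if not 12 <= s.length <= 23:
        raise ValueError(f"spacer length {s.length} outside the 12-23 bp library range")
    if _BSAI in s.seq or _BSAI_RC in s.seq:
        raise ValueError(
            f"spacer {s.seq} contains an internal BsaI site ({_BSAI}/{_BSAI_RC}); "
            "it would be destroyed during Golden Gate assembly"
        )
    return OligoDesign(top_oligo=_TOP_PREFIX + s.seq + _TOP_SUFFIX, helper_oligo=_HELPER)


def simulate_bsai(design: OligoDesign) -> BsaIInsert:
    """In-silico BsaI digestion of the annealed, extended oligo duplex.

    BsaI cuts one base downstream of GGTCTC leaving 4-nt 5' overhangs:
    GACA on the -35-proximal side and TATA on the -10-proximal side.
    """
    seq = design.top_oligo
    if not seq.startswith(_TOP_PREFIX) or not seq.endswith(_TOP_SUFFIX):
        raise ValueError("top oligo does not match the fixed library scheme")
    p = seq.rindex(_BSAI_RC)
    left = seq[len(_BSAI) + 1 : len(_BSAI) + 5]
    right = seq[p - 5 : p - 1]
    spacer = seq[len(_TOP_PREFIX) : p - 5]
    return BsaIInsert(spacer=spacer, overhang_left=left, overhang_right=right)


# ---------------------------------------------------------------------------
# native-promoter fixtures (RegulonDB-like table + RNA-seq-like counts)

#: native spacer-length frequencies, peaked at 17 bp within the 15-21 bp range
_NATIVE_LENGTH_P = {15: 0.06, 16: 0.17, 17: 0.42, 18: 0.22, 19: 0.08, 20: 0.03, 21: 0.02}


def _mutate(rng: np.random.Generator, consensus: str, n_mut: int) -> str:
    seq = list(consensus)
    for pos in rng.choice(len(seq), size=n_mut, replace=False):
        seq[pos] = rng.choice([b for b in "ACGT" if b != seq[pos]])
    return "".join(seq)


def make_promoter_table(n: int = 200, seed: int = 0) -> pd.DataFrame:
    """Synthetic RegulonDB-dialect promoter table (sigma70, native lengths).

    Columns: promoter_id, gene, minus35, spacer, minus10, sigma.  Hexamers
    carry 0-5 mutations total so the consensus filter has work to do.
    """
    rng = substream(seed, "promoter_table")
    lengths = rng.choice(
        list(_NATIVE_LENGTH_P), size=n, p=list(_NATIVE_LENGTH_P.values())
    )
    rows = []
    for i, L in enumerate(lengths):
        total_mut = int(rng.choice([0, 1, 2, 3, 4, 5], p=[0.1, 0.25, 0.3, 0.2, 0.1, 0.05]))
        m10_mut = int(rng.integers(0, total_mut + 1))
        rows.append(
            {
                "promoter_id": f"p{i:04d}",
                "gene": f"gene{i:04d}",
                "minus35": _mutate(rng, MINUS35_CONSENSUS, total_mut - m10_mut),
                "spacer": "".join(rng.choice(BASES, size=int(L))),
                "minus10": _mutate(rng, MINUS10_CONSENSUS, m10_mut),
                "sigma": "Sigma70",
            }
        )
    return pd.DataFrame(rows)


def make_gene_counts(
    promoters: pd.DataFrame,
    timepoints: int = 6,
    depth: int = 2_000_000,
    seed: int = 0,
    cfg: SimConfig | None = None,
) -> pd.DataFrame:
    """RNA-seq-like count table for the genes behind a promoter table.

    Expression is tied to spacer length through the library base curve
    (native lengths only) times a lognormal gene effect, modulated over
    time, so maximal relative expression recovers a length-strength trend.
    """
    cfg = cfg or SimConfig()
    rng = substream(seed, "gene_counts")
    curve = cfg.strength.base_curve
    strength = np.array(
        [
            curve.get(len(sp), 100.0) * np.exp(rng.normal(0.0, cfg.strength.sigma_log))
            for sp in promoters["spacer"]
        ]
    )
    n = len(promoters)
    cds_len = rng.integers(300, 3000, size=n)
    profile = np.exp(-0.5 * ((np.arange(timepoints) - rng.uniform(0, timepoints - 1, (n, 1))) / 1.5) ** 2)
    expected = strength[:, None] * (0.2 + profile) * cds_len[:, None]
    out = {"gene": promoters["gene"].to_numpy(), "cds_length": cds_len}
    for tp in range(timepoints):
        lam = expected[:, tp] / expected[:, tp].sum() * depth
        out[f"t{tp}"] = rng.poisson(lam)
    return pd.DataFrame(out)
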