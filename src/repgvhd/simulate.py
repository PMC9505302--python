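"""Synthetic repertoires and clinical cohorts for pipeline testing.

Real TRB repertoires have heavily skewed clone-size distributions; GVHD
is associated with expansion of a few dominant clones (lower inverse
Simpson diversity, fewer clones filling the top 25% of clonal space, a
larger top-20 proportion).  The generators here reproduce exactly that
structure and nothing more:

* clone *masses* drawn from a power law (default tail exponent 2.0,
  typical of TRB clone-size fits) or a log-normal;
* an expansion factor ``E >= 1`` multiplying the masses of the top ``m``
  clones — ``E = 1`` is a healthy-like repertoire, large ``E`` the
  clonally expanded GVHD signature;
* read counts multinomial over the normalized masses (100,000 reads by
  default, so the 20,000-read downsampling stage is always exercised);
* random in-frame CDR3 nucleotide sequences (27–51 nt) with uniform
  V/J calls — no V(D)J recombination statistics, no sequencing error.

Cohorts draw per-subject cause-specific event times (endpoint, relapse,
non-relapse mortality) from exponential hazards, first event wins, with
administrative censoring at 36 months; a linkage coefficient ties clonal
expansion to the endpoint hazard so the downstream classification →
cumulative-incidence analysis has a known truth to recover.

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import pandas as pd

from .errors import ValidationError
from .survival import CENSORED, COMPETING, EVENT, FOLLOW_UP_CAP
from .tables import COLUMNS, ClonotypeTable

# ----------------------------------------------------------------------
# fast random CDR3 generation
# ----------------------------------------------------------------------

_NT = np.frombuffer(b"ACGT", dtype="S1")

# standard codon table indexed by 16*a + 4*b + c over (A, C, G, T)
_CODON_AA = np.array(list(
    "KNKNTTTTRSRSIIMIQHQHPPPPRRRRLLLLEDEDAAAAGGGGVVVV*Y*YSSSS*CWCLFLF"
), dtype="S1")


def _random_cdr3(rng: np.random.Generator, n: int) -> tuple[list[str], list[str]]:
    """n random in-frame CDR3s (27-51 nt) and their translations."""
    lengths = rng.choice(np.arange(27, 52, 3), size=n)
    flat = rng.integers(0, 4, size=int(lengths.sum()))
    ends = np.cumsum(lengths)
    starts = ends - lengths
    nt_chars = _NT[flat]
    aa_flat = _CODON_AA[16 * flat[0::3] + 4 * flat[1::3] + flat[2::3]]
    nts, aas = [], []
    for s, e in zip(starts, ends):
        nts.append(nt_chars[s:e].tobytes().decode())
        aas.append(aa_flat[s // 3:e // 3].tobytes().decode())
    return nts, aas


_V_CALLS = [f"TRBV{i}" for i in range(1, 31)]
_J_CALLS = [f"TRBJ{i}-{j}" for i in (1, 2) for j in range(1, 7)]


# ----------------------------------------------------------------------
# configs
# ----------------------------------------------------------------------

@dataclass
class RepertoireSimConfig:
    """Parameters of one synthetic repertoire.

    ``clone_law`` is the distribution of latent clone masses:
    ``"power_law"`` with tail exponent ``alpha`` (mass ~ Pareto, density
    ∝ x^-alpha for x >= 1) or ``"log_normal"`` with ``mu, sigma``.
    ``expansion_factor`` multiplies the masses of the ``n_expanded``
    largest clones; 1.0 means no expansion.
    """

    n_clones: int = 2000
    clone_law: Literal["power_law", "log_normal"] = "power_law"
    alpha: float = 2.0
    mu: float = 0.0
    sigma: float = 1.5
    expansion_factor: float = 1.0
    n_expanded: int = 5
    total_reads: int = 100_000
    seed: int = 0

    def validate(self) -> None:
        if self.n_clones < 1:
            raise ValidationError("n_clones must be >= 1")
        if self.expansion_factor < 1.0:
            raise ValidationError("expansion_factor must be >= 1")
        if self.n_expanded > self.n_clones:
            raise ValidationError("n_expanded cannot exceed n_clones")
        if self.total_reads < 1:
            raise ValidationError("total_reads must be >= 1")
        if self.clone_law == "power_law" and self.alpha <= 1.0:
            raise ValidationError("power-law exponent alpha must be > 1")
        if self.clone_law == "log_normal" and self.sigma <= 0:
            raise ValidationError("log-normal sigma must be > 0")
        if self.clone_law not in ("power_law", "log_normal"):
            raise ValidationError(f"unknown clone law: {self.clone_law!r}")


@dataclass
class CohortSimConfig:
    """Parameters of a synthetic two-arm cohort with competing risks.

    Hazards are constant cause-specific rates in events/month.  The
    endpoint hazard of clonally expanded subjects is the healthy-like
    hazard times ``hazard_ratio_expanded`` (the linkage coefficient);
    relapse and non-relapse mortality act as competing events.  Default
    rates give event frequencies over 36 months comparable to a DLI
    cohort (GVHD in roughly half the subjects).
    """

    n_expanded: int = 20
    n_healthy_like: int = 20
    hazard_endpoint: float = 0.03          # healthy-like GVHD hazard, /month
    hazard_ratio_expanded: float = 2.5     # linkage: expansion -> endpoint risk
    hazard_relapse: float = 0.02
    hazard_nrm: float = 0.01
    follow_up: float = FOLLOW_UP_CAP
    expanded_factor: float = 20.0          # repertoire E for expanded subjects
    healthy_factor: float = 1.0
    repertoire: RepertoireSimConfig = field(default_factory=RepertoireSimConfig)
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_expanded, self.n_healthy_like) < 1:
            raise ValidationError("group sizes must be >= 1")
        hazards = (self.hazard_endpoint, self.hazard_relapse, self.hazard_nrm)
        if any(h < 0 for h in hazards) or self.hazard_ratio_expanded < 0:
            raise ValidationError("hazards must be non-negative")
        if all(h == 0 for h in hazards) and not np.isfinite(self.follow_up):
            raise ValidationError("all-zero hazards need a finite censoring horizon")


# ----------------------------------------------------------------------
# generators
# ----------------------------------------------------------------------

def _clone_masses(config: RepertoireSimConfig, rng: np.random.Generator) -> np.ndarray:
    if config.clone_law == "power_law":
        masses = rng.pareto(config.alpha - 1.0, size=config.n_clones) + 1.0
    else:
        masses = rng.lognormal(config.mu, config.sigma, size=config.n_clones)
    if config.expansion_factor > 1.0 and config.n_expanded > 0:
        top = np.argsort(masses)[-config.n_expanded:]
        masses = masses.copy()
        masses[top] *= config.expansion_factor
    return masses


def _assemble_table(config: RepertoireSimConfig, rng: np.random.Generator,
                    masses: np.ndarray, sample_id: str,
                    **meta) -> ClonotypeTable:
    p = masses / masses.sum()
    counts = rng.multinomial(config.total_reads, p)
    nts, aas = _random_cdr3(rng, config.n_clones)
    df = pd.DataFrame({
        "count": counts,
        "freq": 0.0,
        "cdr3nt": nts,
        "cdr3aa": aas,
        "v": rng.choice(_V_CALLS, size=config.n_clones),
        "d": ".",
        "j": rng.choice(_J_CALLS, size=config.n_clones),
    })[COLUMNS]
    df = df[df["count"] > 0].reset_index(drop=True)
    return ClonotypeTable(sample_id=sample_id, data=df, **meta)


def simulate_repertoire(config: RepertoireSimConfig,
                        sample_id: str = "sim", **meta) -> ClonotypeTable:
    """One synthetic clonotype table; deterministic per config.seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    masses = _clone_masses(config, rng)
    return _assemble_table(config, rng, masses, sample_id, **meta)


def simulate_longitudinal_patient(
    base: RepertoireSimConfig,
    post_expansion: float,
    seed: int | None = None,
) -> tuple[ClonotypeTable, ClonotypeTable]:
    """Pre/post sample pair sharing one clone pool.

    The post table re-weights the top ``base.n_expanded`` clone masses by
    ``post_expansion`` (1.0 reproduces the pre distribution); clonotype
    keys overlap by construction since both draws share the pool.
    """
    base.validate()
    if post_expansion < 1.0:
        raise ValidationError("post_expansion must be >= 1")
    rng = np.random.default_rng(base.seed if seed is None else seed)
    masses = _clone_masses(replace(base, expansion_factor=1.0), rng)
    nts, aas = _random_cdr3(rng, base.n_clones)
    v = rng.choice(_V_CALLS, size=base.n_clones)
    j = rng.choice(_J_CALLS, size=base.n_clones)

    def draw(m: np.ndarray, sid: str, tp: int) -> ClonotypeTable:
        counts = rng.multinomial(base.total_reads, m / m.sum())
        df = pd.DataFrame({"count": counts, "freq": 0.0, "cdr3nt": nts,
                           "cdr3aa": aas, "v": v, "d": ".", "j": j})[COLUMNS]
        df = df[df["count"] > 0].reset_index(drop=True)
        return ClonotypeTable(sample_id=sid, timepoint=tp, data=df)

    pre = draw(masses, "pre", -30)
    post_masses = masses.copy()
    if post_expansion > 1.0 and base.n_expanded > 0:
        top = np.argsort(masses)[-base.n_expanded:]
        post_masses[top] *= post_expansion
    post = draw(post_masses, "post", 9)
    return pre, post


def simulate_cohort(
    config: CohortSimConfig,
    generate_repertoires: bool = True,
) -> tuple[pd.DataFrame, dict[str, ClonotypeTable]]:
    """Two-arm cohort: event table plus baseline repertoires.

    Returns ``(events, repertoires)``.  `events` has columns
    ``subject_id, group, time, event, expansion_factor`` with event
    codes for the endpoint ("event"), competing relapse/NRM
    ("competing") and administrative censoring at ``config.follow_up``.
    `repertoires` maps subject_id to a baseline clonotype table drawn
    with that subject's expansion factor (empty dict when
    ``generate_repertoires`` is false).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    rows = []
    repertoires: dict[str, ClonotypeTable] = {}
    groups = [("expanded", config.n_expanded,
               config.hazard_endpoint * config.hazard_ratio_expanded,
               config.expanded_factor),
              ("healthy_like", config.n_healthy_like,
               config.hazard_endpoint, config.healthy_factor)]
    for group, n, h_end, e_factor in groups:
        for i in range(n):
            sid = f"{group}_{i:03d}"
            hazards = {EVENT: h_end, COMPETING + ":relapse": config.hazard_relapse,
                       COMPETING + ":nrm": config.hazard_nrm}
            times = {k: rng.exponential(1.0 / h) if h > 0 else np.inf
                     for k, h in hazards.items()}
            cause, t = min(times.items(), key=lambda kv: kv[1])
            if t > config.follow_up:
                cause, t = CENSORED, config.follow_up
            rows.append({"subject_id": sid, "group": group,
                         "time": float(t),
                         "event": cause.split(":")[0],
                         "cause": cause.split(":")[-1] if ":" in cause else cause,
                         "expansion_factor": e_factor})
            if generate_repertoires:
                rep_cfg = replace(config.repertoire,
                                  expansion_factor=e_factor,
                                  seed=int(rng.integers(0, 2**31 - 1)))
                repertoires[sid] = simulate_repertoire(
                    rep_cfg, sample_id=sid, subject_id=sid, timepoint=14)
    return pd.DataFrame(rows), repertoires
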