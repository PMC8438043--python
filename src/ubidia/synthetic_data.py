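"""Seeded generators for synthetic DIA runs and time-course experiments.

Two generators make every downstream stage testable without raw
instrument data:

* :func:`simulate_dia_run` draws per-fragment extracted ion
  chromatograms for a run with known ground truth — Gaussian elution
  peaks sampled at ~4–5 points per peak, Dirichlet fragment intensity
  weights, multiplicative lognormal noise, an additive baseline, and
  optional co-fragmenting interference.  Precursors that are searched
  but not present yield baseline-only traces, which is what a decoy or a
  false target looks like to the scorer.

* :func:`simulate_timecourse` produces ubiquitinome and proteome
  intensity matrices for a drug-vs-DMSO time course with planted
  effects: a subset of proteins is "ubiquitinated early, degraded
  later" (the degradative class), another subset is ubiquitinated but
  never degraded, the rest are null.  Lognormal abundance noise
  (CV ≈ 10 %) and intensity-dependent missingness emulate label-free
  DIA quantification.

Both generators are pure functions of (truth, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .masses_digestion import (
    MOD_DELTAS,
    FragmentAnnotation,
    ModifiedPeptide,
    Precursor,
    ProteinEntry,
    precursor_mz,
    select_fragments,
)

__all__ = [
    "GroundTruthRun",
    "TimecourseTruth",
    "ChromatogramSet",
    "random_proteome",
    "generate_decoy",
    "make_ground_truth",
    "simulate_dia_run",
    "make_timecourse_truth",
    "simulate_timecourse",
]


# ---------------------------------------------------------------------------
# DIA run ground truth and simulation
# ---------------------------------------------------------------------------

@dataclass
class ChromatogramSet:
    """Aligned fragment/MS1 traces for one searched precursor in one run."""

    rt: np.ndarray                       # shared grid, seconds
    fragments: tuple[FragmentAnnotation, ...]
    fragment_traces: np.ndarray          # (n_fragments, n_points), >= 0
    ms1_trace: np.ndarray                # (n_points,)

    def __post_init__(self) -> None:
        if self.fragment_traces.shape != (len(self.fragments), self.rt.size):
            raise ValueError("trace matrix does not match fragments × grid")
        if self.ms1_trace.shape != self.rt.shape:
            raise ValueError("MS1 trace does not match the RT grid")


@dataclass
class GroundTruthRun:
    """What is actually in a simulated run."""

    present: dict[str, tuple[float, float, float]]  # id -> (apex_rt, sigma, abundance)
    searched: list[Precursor]                       # targets + decoys
    rt_grid: np.ndarray
    seed: int
    rt_shift: tuple[float, float] = (0.0, 1.0)      # apex' = a + b * apex
    # relative fragment intensities are a property of the peptide, not of
    # the run: drawn once per present precursor and shared across runs
    fragment_weights: dict[str, np.ndarray] = field(default_factory=dict)


def random_proteome(
    n_proteins: int,
    mean_length: int = 120,
    seed: int = 0,
) -> list[ProteinEntry]:
    """Random protein sequences with tryptic-like K/R density (~1 in 9)."""
    rng = np.random.default_rng(seed)
    # residue frequencies loosely matching vertebrate proteomes
    alphabet = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    freqs = np.array([
        7.4, 1.5, 5.3, 6.3, 3.9, 7.1, 2.3, 5.3, 6.0, 9.5,
        2.4, 4.4, 5.5, 4.1, 5.2, 7.6, 5.7, 6.5, 1.2, 3.2,
    ])
    freqs = freqs / freqs.sum()
    proteins = []
    for i in range(n_proteins):
        length = int(rng.integers(mean_length // 2, mean_length * 3 // 2))
        seq = "".join(rng.choice(alphabet, size=length, p=freqs))
        proteins.append(ProteinEntry(accession=f"SYN{i:05d}", sequence=seq,
                                     description=f"SYN{i:05d} synthetic protein"))
    return proteins


def generate_decoy(precursor: Precursor, target_ids: frozenset[str] | None = None,
                   collision_shift: float = 10.0) -> Precursor:
    """Pseudo-reversed decoy: reverse the sequence keeping the C-terminal
    residue fixed; modifications follow their residues.  If the decoy
    sequence collides with any target sequence (e.g. palindromes), the
    precursor m/z is shifted by a fixed small offset and the collision
    is flagged via a mass-shift pseudo-modification.
    """
    if precursor.decoy:
        raise ValueError("refusing to build a decoy of a decoy")
    pep = precursor.peptide
    n = len(pep.sequence)
    body = pep.sequence[: n - 1]
    rev = body[::-1] + pep.sequence[-1]
    # old position i (1-based, within body) -> new position n-i
    mods = []
    for pos, name, delta in pep.modifications:
        new_pos = pos if pos == n else n - pos
        mods.append((new_pos, name, delta))
    mods.sort()
    collided = target_ids is not None and rev in target_ids
    if collided:
        mods.append((n, "DecoyShift", collision_shift))
    decoy_pep = ModifiedPeptide(
        sequence=rev,
        protein_links=(),
        modifications=tuple(mods),
        missed_cleavages=pep.missed_cleavages,
    )
    frags = select_fragments(decoy_pep, charge=precursor.fragment_annotations[0].charge
                             if precursor.fragment_annotations else 1)
    return Precursor(
        peptide=decoy_pep,
        charge=precursor.charge,
        mz=precursor_mz(decoy_pep, precursor.charge),
        fragment_annotations=frags,
        decoy=True,
    )


def make_ground_truth(
    precursors: list[Precursor],
    n_present: int,
    n_absent: int,
    config=None,
    seed: int = 0,
    rt_shift: tuple[float, float] = (0.0, 1.0),
) -> GroundTruthRun:
    """Pick present/absent targets, pair decoys 1:1, draw apex RTs.

    The same (precursors, seed) always selects the same truth, so
    multi-run experiments share which peptides are really present while
    per-run noise differs via the run seed passed to
    :func:`simulate_dia_run`.
    """
    from .config import RunConfig

    cfg = config or RunConfig()
    rng = np.random.default_rng(seed)
    if n_present + n_absent > len(precursors):
        raise ValueError("not enough precursors in the search space")
    order = rng.permutation(len(precursors))
    chosen = [precursors[i] for i in order[: n_present + n_absent]]
    target_seqs = frozenset(p.peptide.sequence for p in chosen)
    searched: list[Precursor] = []
    for p in chosen:
        searched.append(p)
        searched.append(generate_decoy(p, target_seqs))

    grid = np.arange(0.0, cfg.gradient_length, cfg.cycle_time)
    margin = 6 * cfg.peak_sigma
    present = {}
    weights = {}
    for p in chosen[:n_present]:
        apex = rng.uniform(margin, cfg.gradient_length - margin)
        sigma = cfg.peak_sigma * rng.uniform(0.8, 1.2)
        abundance = float(10 ** rng.uniform(3.0, 5.0))
        present[p.precursor_id] = (float(apex), float(sigma), abundance)
        weights[p.precursor_id] = rng.dirichlet(
            np.full(len(p.fragment_annotations), cfg.dirichlet_alpha)
        )
    return GroundTruthRun(
        present=present, searched=searched, rt_grid=grid, seed=seed,
        rt_shift=rt_shift, fragment_weights=weights,
    )


def simulate_dia_run(
    truth: GroundTruthRun,
    interference_rate: float | None = None,
    noise_cv: float | None = None,
    baseline: float | None = None,
    config=None,
    seed: int | None = None,
    abundance_scale: float = 1.0,
) -> dict[str, ChromatogramSet]:
    """Draw one run: a ChromatogramSet per searched precursor.

    Present precursors get proportional Gaussian fragment traces with
    Dirichlet weights; interference adds a displaced Gaussian to random
    fragments; absent precursors (and decoys) get baseline-only traces.
    Identical (truth, seed) gives bit-identical output.
    """
    from .config import RunConfig

    cfg = config or RunConfig()
    if interference_rate is None:
        interference_rate = cfg.interference_rate
    if not 0.0 <= interference_rate <= 1.0:
        raise ValueError("interference_rate must be in [0, 1]")
    if noise_cv is None:
        noise_cv = cfg.noise_cv
    if baseline is None:
        baseline = cfg.baseline_level
    rng = np.random.default_rng(truth.seed if seed is None else seed)

    grid = truth.rt_grid
    if grid.size == 0:
        raise ValueError("empty RT grid")
    sdlog = np.sqrt(np.log1p(noise_cv**2))
    a, b = truth.rt_shift

    out: dict[str, ChromatogramSet] = {}
    for prec in truth.searched:
        n_frag = len(prec.fragment_annotations)
        traces = np.zeros((n_frag, grid.size))
        ms1 = np.zeros(grid.size)
        info = truth.present.get(prec.precursor_id)
        if info is not None:
            apex, sigma, abundance = info
            abundance = abundance * abundance_scale
            apex = a + b * apex
            weights = truth.fragment_weights.get(prec.precursor_id)
            if weights is None:
                weights = rng.dirichlet(np.full(n_frag, cfg.dirichlet_alpha))
            shape = np.exp(-0.5 * ((grid - apex) / sigma) ** 2)
            traces += abundance * weights[:, None] * shape[None, :]
            ms1 += 0.5 * abundance * shape
            if interference_rate > 0:
                hit = rng.random(n_frag) < interference_rate
                slo, shi = cfg.interference_shift_sigma
                alo, ahi = cfg.interference_amplitude
                for f in np.flatnonzero(hit):
                    shift = rng.uniform(slo, shi) * sigma * rng.choice([-1.0, 1.0])
                    amp = abundance * weights[f] * rng.uniform(alo, ahi)
                    traces[f] += amp * np.exp(
                        -0.5 * ((grid - (apex + shift)) / sigma) ** 2
                    )
            if noise_cv > 0:
                traces *= rng.lognormal(0.0, sdlog, size=traces.shape)
                ms1 *= rng.lognormal(0.0, sdlog, size=ms1.shape)
        if baseline > 0:
            traces += rng.exponential(baseline, size=traces.shape)
            ms1 += rng.exponential(baseline, size=ms1.shape)
        out[prec.precursor_id] = ChromatogramSet(
            rt=grid,
            fragments=prec.fragment_annotations,
            fragment_traces=traces,
            ms1_trace=ms1,
        )
    return out


# ---------------------------------------------------------------------------
# Time-course ground truth and simulation
# ---------------------------------------------------------------------------

@dataclass
class TimecourseTruth:
    design: pd.DataFrame            # sample, condition, time_min, replicate
    site_effects: pd.DataFrame      # peptide × time, true log2 fold change
    protein_effects: pd.DataFrame   # protein × time, true relative abundance
    peptide_protein: pd.Series      # peptide id -> protein accession
    degradative_set: frozenset[str]
    nondegradative_set: frozenset[str]
    site_baseline: pd.Series
    protein_baseline: pd.Series
    cv: float
    dropout_loc: float              # log2-intensity at 50 % dropout
    dropout_scale: float
    seed: int


DEFAULT_TIMES = (15, 60, 120, 240, 360)  # minutes after treatment


def make_timecourse_truth(
    n_proteins: int = 500,
    n_degradative: int = 40,
    n_nondegradative: int = 40,
    n_background_proteins: int = 300,
    replicates: int = 4,
    times: tuple[int, ...] = DEFAULT_TIMES,
    cv: float = 0.10,
    dropout_loc: float = 14.0,
    dropout_scale: float = 1.0,
    seed: int = 0,
) -> TimecourseTruth:
    """Plant a drug-vs-DMSO time course.

    * degradative proteins: ≥1 K-GG site with true log2FC > 1 at the
      earliest drug time point, protein level dropping to ≤ 0.8× control
      at a later time point;
    * non-degradative proteins: sites up the same way, protein flat;
    * everything else: null.

    The ubiquitinome covers ``n_proteins`` (1–3 K-GG peptides each); the
    proteome additionally contains unmodified background proteins.
    """
    if replicates < 2:
        import warnings

        warnings.warn("fewer than 2 replicates: moderated statistics will refuse")
    rng = np.random.default_rng(seed)
    prot_ids = [f"TP{i:05d}" for i in range(n_proteins)]
    deg = set(prot_ids[:n_degradative])
    nondeg = set(prot_ids[n_degradative: n_degradative + n_nondegradative])
    times = tuple(times)
    t_arr = np.array(times, dtype=float)

    peptides, pep_protein = [], []
    for pid in prot_ids:
        for j in range(int(rng.integers(1, 4))):
            peptides.append(f"{pid}_KGG{j}")
            pep_protein.append(pid)
    pep_protein = pd.Series(pep_protein, index=peptides, name="protein")

    site_fc = pd.DataFrame(0.0, index=peptides, columns=list(times))
    for pid in sorted(deg | nondeg):
        members = pep_protein.index[pep_protein == pid]
        # one or two responding sites per regulated protein: regulation is
        # sparse at the feature level, as in real DUB-inhibition data, so
        # median sample scaling stays valid downstream
        n_up = min(len(members), 1 + int(rng.random() < 0.3))
        for pep in rng.choice(members, size=n_up, replace=False):
            fc0 = rng.uniform(1.5, 2.8)  # clearly > twofold at the earliest time
            peak_t = float(rng.choice(t_arr[:3]))
            shape = np.exp(-0.5 * ((np.log(t_arr) - np.log(peak_t)) / 1.5) ** 2)
            site_fc.loc[pep] = fc0 * shape / shape[0]

    prot_level = pd.DataFrame(1.0, index=prot_ids, columns=list(times))
    for pid in sorted(deg):
        floor = rng.uniform(0.45, 0.72)
        onset = float(rng.choice(t_arr[1:-1]))  # degradation completes in-window
        level = 1.0 - (1.0 - floor) / (1.0 + np.exp(-(t_arr - onset) / 40.0))
        level = np.minimum(level, np.where(t_arr >= onset, 0.78, 1.0))
        prot_level.loc[pid] = level

    bg_ids = [f"BG{i:05d}" for i in range(n_background_proteins)]
    prot_level = pd.concat(
        [prot_level, pd.DataFrame(1.0, index=bg_ids, columns=list(times))]
    )

    rows = []
    for cond in ("DMSO", "drug"):
        for t in times:
            for r in range(1, replicates + 1):
                rows.append({
                    "sample": f"{cond}_t{t}_r{r}",
                    "condition": cond,
                    "time_min": t,
                    "replicate": r,
                })
    design = pd.DataFrame(rows).set_index("sample")

    site_baseline = pd.Series(
        10 ** rng.uniform(4.5, 6.5, size=len(peptides)), index=peptides
    )
    protein_baseline = pd.Series(
        10 ** rng.uniform(5.0, 7.0, size=len(prot_level)), index=prot_level.index
    )
    return TimecourseTruth(
        design=design,
        site_effects=site_fc,
        protein_effects=prot_level,
        peptide_protein=pep_protein,
        degradative_set=frozenset(deg),
        nondegradative_set=frozenset(nondeg),
        site_baseline=site_baseline,
        protein_baseline=protein_baseline,
        cv=cv,
        dropout_loc=dropout_loc,
        dropout_scale=dropout_scale,
        seed=seed,
    )


def _simulate_matrix(
    baseline: pd.Series,
    effect_log2: pd.DataFrame,
    design: pd.DataFrame,
    cv: float,
    dropout_loc: float,
    dropout_scale: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """intensity = baseline × effect × lognormal(cv), then MNAR dropout."""
    features = baseline.index
    sdlog = np.sqrt(np.log1p(cv**2)) if cv > 0 else 0.0
    cols = {}
    for sample, row in design.iterrows():
        eff = np.ones(len(features))
        if row["condition"] == "drug":
            eff = 2.0 ** effect_log2[row["time_min"]].to_numpy()
        vals = baseline.to_numpy() * eff
        if sdlog > 0:
            vals = vals * rng.lognormal(0.0, sdlog, size=len(features))
        cols[sample] = vals
    mat = pd.DataFrame(cols, index=features)
    if dropout_scale > 0:
        logi = np.log2(mat.to_numpy())
        p_miss = 1.0 / (1.0 + np.exp((logi - dropout_loc) / dropout_scale))
        miss = rng.random(mat.shape) < p_miss
        arr = mat.to_numpy()
        arr[miss] = np.nan
        mat = pd.DataFrame(arr, index=mat.index, columns=mat.columns)
    return mat


def simulate_timecourse(truth: TimecourseTruth, seed: int | None = None):
    """Draw (ubiquitinome QuantTable, proteome QuantTable, truth tables)."""
    from .quantification import QuantTable

    rng = np.random.default_rng(truth.seed if seed is None else seed)
    ubi = _simulate_matrix(
        truth.site_baseline, truth.site_effects, truth.design,
        truth.cv, truth.dropout_loc, truth.dropout_scale, rng,
    )
    prot_fc = np.log2(truth.protein_effects)
    prot = _simulate_matrix(
        truth.protein_baseline, prot_fc, truth.design,
        truth.cv, truth.dropout_loc, truth.dropout_scale, rng,
    )
    ubi_meta = pd.DataFrame({
        "protein": truth.peptide_protein,
        "kgg_site": 1,
    })
    prot_meta = pd.DataFrame(index=prot.index)
    ubi_qt = QuantTable(level="peptide", data=ubi, feature_meta=ubi_meta,
                        sample_meta=truth.design)
    prot_qt = QuantTable(level="protein", data=prot, feature_meta=prot_meta,
                         sample_meta=truth.design)
    return ubi_qt, prot_qt, truth
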