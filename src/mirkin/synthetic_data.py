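"""Synthetic differentiation campaigns with known ground truth.

Emulates the structure of the study's recordings: two conditions (WT and a
GCNF knock-out in which GCNF is identically zero), miRNAs recorded on days
0/1/3/6 in three qualitative classes (HL high-then-low, LH low-then-high,
TR transient), mRNAs on days 0/3/6, proteins on days 0/1.5/3/6 with
per-lane actin loading controls, and replicate-level multiplicative
log-normal noise.  Downstream mRNA/protein profiles are forward-simulated
from planted kinetic parameters, so every stage of the pipeline — reading,
normalization, interpolation, enumeration, fitting, validation — can be
exercised end to end against a known answer.

Decoy pairs give the validation stage a falsifiable negative class: they
appear in the target table, but their downstream mRNA follows a transient
template with zero coupling to the miRNA, shaped so that no admissible
kinetic model reproduces it (its mid-course peak opposes the committed
fraction implied by its own regulators).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .architectures import (
    GeneTFSpec,
    TargetTable,
    TFConfig,
    TranscrDegrArch,
    TranslInhibArch,
)
from .errors import SimSpecError
from .kinetics import HillParams, TDParams, TIParams, predict_downstream
from .profiles import Condition, Kind, Profile, RawRecording, TimeGrid, interpolate_profile

__all__ = [
    "SimSpec",
    "SimOutput",
    "PlantedInteraction",
    "simulate_mirna_profiles",
    "simulate_downstream",
    "recovery_fixture",
    "default_recovery_spec",
    "MIRNA_DAYS",
    "MRNA_DAYS",
    "PROTEIN_DAYS",
]

MIRNA_DAYS = (0.0, 1.0, 3.0, 6.0)
MRNA_DAYS = (0.0, 3.0, 6.0)
PROTEIN_DAYS = (0.0, 1.5, 3.0, 6.0)

#: proportions of the HL / LH / TR miRNA classes observed in the study
#: (105, 78 and 46 of 229 classified miRNAs)
DEFAULT_CLASS_MIX = (105 / 229, 78 / 229, 46 / 229)

_CLASS_ORDER = ("HL", "LH", "TR")


@dataclass(frozen=True)
class PlantedInteraction:
    """One true interaction: an architecture, its kinetic parameters and the
    downstream initial level per condition.

    ``initial=None`` starts the downstream at its day-0 kinetic equilibrium
    (synthesis balancing removal), emulating cells at steady state before
    differentiation is induced; this also keeps the sparse day-grid sampling
    faithful, since the trajectory then tracks its moving equilibrium
    instead of opening with a transient the recorded days cannot resolve.
    """

    arch: TranscrDegrArch | TranslInhibArch
    params: TDParams | TIParams
    initial: Mapping[Condition, float] | None = None


@dataclass(frozen=True)
class SimSpec:
    """Specification of one synthetic campaign; identical specs (including
    the seed) always produce bit-identical output."""

    seed: int = 0
    n_mirnas: int = 12
    genes: tuple[str, ...] = ()
    class_mix: tuple[float, float, float] = DEFAULT_CLASS_MIX
    noise_sigma: float = 0.05
    n_replicates: Mapping[Kind, int] = field(
        default_factory=lambda: {Kind.MIRNA: 6, Kind.MRNA: 3, Kind.PROTEIN: 1}
    )
    planted: tuple[PlantedInteraction, ...] = ()
    decoy_pairs: tuple[tuple[str, str], ...] = ()  # (mirna, decoy gene)
    knockout_protein: str = "GCNF"

    def __post_init__(self):
        if abs(sum(self.class_mix) - 1.0) > 1e-9:
            raise SimSpecError("class-mix proportions must sum to 1")
        if self.noise_sigma < 0:
            raise SimSpecError("noise sigma must be nonnegative")
        ids = set(mirna_ids(self.n_mirnas))
        for p in self.planted:
            for m in p.arch.mirnas:
                if m not in ids:
                    raise SimSpecError(f"planted miRNA {m!r} not among the declared miRNAs")


@dataclass(frozen=True)
class SimOutput:
    recordings: tuple[RawRecording, ...]
    target_table: TargetTable
    truth: tuple[PlantedInteraction, ...]
    tf_config: TFConfig


def mirna_ids(n: int) -> list[str]:
    return [f"mir-{i:03d}" for i in range(1, n + 1)]


def allocate_classes(n: int, mix: Sequence[float]) -> list[str]:
    """Deterministic largest-remainder allocation of n miRNAs to HL/LH/TR."""
    raw = [n * p for p in mix]
    counts = [int(np.floor(r)) for r in raw]
    rem = n - sum(counts)
    order = sorted(range(3), key=lambda i: (-(raw[i] - counts[i]), i))
    for i in order[:rem]:
        counts[i] += 1
    out = []
    for cls, k in zip(_CLASS_ORDER, counts):
        out.extend([cls] * k)
    return out


@dataclass(frozen=True)
class Template:
    """Noiseless knot values of one molecule on its recorded day grid."""

    molecule_id: str
    kind: Kind
    days: tuple[float, ...]
    values: Mapping[Condition, tuple[float, ...]]  # per condition


def simulate_mirna_profiles(spec: SimSpec) -> dict[str, tuple[str, Template]]:
    """Seeded noiseless miRNA templates per class on days 0/1/3/6.

    HL templates decrease strictly from a high day-0 level, LH increase
    strictly, TR rise to a transient peak and fall back.  Identical in both
    conditions (noise is applied later, per replicate).
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 101]))
    classes = allocate_classes(spec.n_mirnas, spec.class_mix)
    out: dict[str, tuple[str, Template]] = {}
    for mid, cls in zip(mirna_ids(spec.n_mirnas), classes):
        amp = float(rng.uniform(300.0, 3000.0))
        if cls == "HL":
            v0 = amp
            v1 = v0 * rng.uniform(0.70, 0.95)
            v3 = v1 * rng.uniform(0.35, 0.60)
            v6 = v3 * rng.uniform(0.10, 0.40)
        elif cls == "LH":
            v0 = amp * rng.uniform(0.05, 0.15)
            v1 = v0 * rng.uniform(1.3, 2.0)
            v3 = v1 * rng.uniform(1.5, 2.5)
            v6 = v3 * rng.uniform(1.3, 2.0)
        else:  # TR: unimodal, peak on day 1 or 3
            peak_day = rng.choice([1.0, 3.0])
            lo0 = amp * rng.uniform(0.10, 0.30)
            lo6 = amp * rng.uniform(0.10, 0.30)
            if peak_day == 1.0:
                v0, v1, v3, v6 = lo0, amp, amp * rng.uniform(0.4, 0.7), lo6
            else:
                v0, v1, v3, v6 = lo0, amp * rng.uniform(0.4, 0.7), amp, lo6
        vals = tuple(float(v) for v in (v0, v1, v3, v6))
        tpl = Template(
            molecule_id=mid,
            kind=Kind.MIRNA,
            days=MIRNA_DAYS,
            values={Condition.WT: vals, Condition.KO: vals},
        )
        out[mid] = (cls, tpl)
    return out


#: qualitative protein shapes on days 0/1.5/3/6, mirroring the Western-blot
#: description: Oct4/Nanog fall sharply in WT and slowly in the knock-out,
#: Sox2 collapses after day 1.5 in WT, GCNF peaks at day 3 in WT and is
#: identically zero in the knock-out.
_PROTEIN_SHAPES: dict[str, dict[Condition, tuple[float, ...] | None]] = {
    "GCNF": {Condition.WT: (0.25, 0.70, 1.00, 0.30), Condition.KO: None},
    "Oct4": {Condition.WT: (1.00, 0.62, 0.30, 0.10), Condition.KO: (1.00, 0.95, 0.88, 0.74)},
    "Nanog": {Condition.WT: (1.00, 0.55, 0.25, 0.08), Condition.KO: (1.00, 0.93, 0.85, 0.70)},
    "Sox2": {Condition.WT: (1.00, 0.07, 0.03, 0.02), Condition.KO: (1.00, 0.90, 0.78, 0.62)},
}
_GENERIC_SHAPE = {Condition.WT: (1.00, 0.70, 0.40, 0.15), Condition.KO: (1.00, 0.85, 0.65, 0.40)}


def _protein_template(pid: str, rng: np.random.Generator, knockout: str) -> Template:
    shapes = _PROTEIN_SHAPES.get(pid, _GENERIC_SHAPE)
    amp = float(rng.uniform(0.5, 2.0))
    values = {}
    for cond in (Condition.WT, Condition.KO):
        shape = shapes.get(cond)
        if pid == knockout and cond is Condition.KO:
            shape = None
        if shape is None:
            values[cond] = (0.0, 0.0, 0.0, 0.0)
        else:
            values[cond] = tuple(float(amp * s) for s in shape)
    return Template(pid, Kind.PROTEIN, PROTEIN_DAYS, values)


def _ti_gene_mrna_template(gene: str, rng: np.random.Generator) -> Template:
    """mRNA of a translation-inhibition gene on days 0/3/6.

    The transcript collapses in WT (Sox2-like) so that, once synthesis is
    depleted, the protein's late decline identifies its decay rate — the
    identifiability the decay pre-estimation step relies on.  The KO
    transcript declines only mildly.
    """
    amp = float(rng.uniform(500.0, 2000.0))
    wt = (amp, amp * rng.uniform(0.08, 0.15), amp * rng.uniform(0.02, 0.05))
    ko = (amp, amp * rng.uniform(0.7, 0.9), amp * rng.uniform(0.5, 0.7))
    return Template(gene, Kind.MRNA, MRNA_DAYS, {Condition.WT: wt, Condition.KO: ko})


def _decoy_mrna_template(gene: str, rng: np.random.Generator) -> Template:
    """Decoy downstream: a strong mid-course peak uncoupled from any miRNA."""
    amp = float(rng.uniform(400.0, 1200.0))
    wt = (amp * 0.12, amp, amp * rng.uniform(0.04, 0.08))
    ko = (amp * 0.12, amp * rng.uniform(0.9, 1.1), amp * rng.uniform(0.04, 0.08))
    return Template(gene, Kind.MRNA, MRNA_DAYS, {Condition.WT: wt, Condition.KO: ko})


def _planted_molecules(spec: SimSpec) -> tuple[set[str], set[str], set[str]]:
    """(regulator proteins, TI genes, downstream TD genes) of the planted set."""
    proteins, ti_genes, td_genes = set(), set(), set()
    for p in spec.planted:
        if isinstance(p.arch, TranscrDegrArch):
            proteins.update(p.arch.regulator_proteins)
            td_genes.add(p.arch.gene)
        else:
            ti_genes.add(p.arch.gene)
    return proteins, ti_genes, td_genes


def _equilibrium_initial(
    p: PlantedInteraction, upstream: Mapping[str, np.ndarray], cond: Condition
) -> float:
    """Day-0 steady state of the planted equation: synthesis / removal."""
    from .kinetics import committed_fraction, hill_impact

    if isinstance(p.arch, TranscrDegrArch):
        rep = sum(hill_impact(upstream[r][0], p.params.hill[r]) for r in p.arch.rep_proteins)
        act = sum(hill_impact(a, p.params.hill[aid]) for aid, a in
                  ((aid, upstream[aid][0]) for aid in p.arch.act_proteins))
        F0 = committed_fraction(rep, act, bool(p.arch.act_proteins))
        M0 = sum(upstream[m][0] for m in p.arch.mirnas)
        removal = p.params.k_react * M0 + p.params.k_deg
        if removal <= 0:
            raise SimSpecError("equilibrium start needs a positive removal rate")
        return p.params.k_transcr * F0 / removal
    rep = sum(hill_impact(upstream[m][0], p.params.hill[m]) for m in p.arch.mirnas)
    kd = p.params.decay_for(cond)
    if kd <= 0:
        raise SimSpecError("equilibrium start needs a positive decay rate")
    return p.params.k_transl * upstream[p.arch.gene][0] / (1.0 + rep) / kd


def _grid_profiles(
    templates: Mapping[str, Template], cond: Condition, grid: TimeGrid
) -> dict[str, np.ndarray]:
    out = {}
    for mid, tpl in templates.items():
        vals = np.asarray(tpl.values[cond], dtype=float)
        if np.all(vals == 0):
            out[mid] = np.zeros(len(grid))
        else:
            out[mid] = interpolate_profile(tpl.days, vals, grid)
    return out


def _sample_days(trajectory: np.ndarray, grid: TimeGrid, days: Sequence[float]) -> np.ndarray:
    from scipy.interpolate import PchipInterpolator

    return np.maximum(PchipInterpolator(grid.array, trajectory)(np.asarray(days)), 0.0)


def simulate_downstream(spec: SimSpec) -> SimOutput:
    """Generate the complete synthetic campaign.

    Upstream miRNA/protein/mRNA templates are interpolated to the common
    grid; each planted equation is integrated at a fine step (60 substeps
    per grid interval) against those upstream trajectories, separately per
    condition with the knock-out protein forced to zero; all molecules are
    then recorded on their day grids with replicate-level mean-one
    log-normal noise, proteins as raw intensities alongside actin lanes.
    """
    grid = TimeGrid()
    rng_prot = np.random.default_rng(np.random.SeedSequence([spec.seed, 202]))
    rng_noise = np.random.default_rng(np.random.SeedSequence([spec.seed, 303]))

    mirnas = simulate_mirna_profiles(spec)
    templates: dict[str, Template] = {mid: tpl for mid, (_, tpl) in mirnas.items()}

    proteins, ti_genes, _ = _planted_molecules(spec)
    for pid in sorted(proteins):
        templates[pid] = _protein_template(pid, rng_prot, spec.knockout_protein)
    for gene in sorted(ti_genes):
        templates[gene] = _ti_gene_mrna_template(gene, rng_prot)
    decoy_genes = sorted({g for _, g in spec.decoy_pairs})
    for gene in decoy_genes:
        templates[gene] = _decoy_mrna_template(gene, rng_prot)

    # forward-simulate every planted downstream per condition
    downstream: dict[tuple[str, Kind, Condition], np.ndarray] = {}
    for cond in (Condition.WT, Condition.KO):
        upstream = _grid_profiles(templates, cond, grid)
        for p in spec.planted:
            if p.initial is None:
                y0 = _equilibrium_initial(p, upstream, cond)
            else:
                y0 = p.initial[cond]
            traj = predict_downstream(
                p.arch,
                p.params,
                upstream,
                grid,
                initial_value=y0,
                substeps=60,
                condition=cond,
            )
            kind = Kind.MRNA if isinstance(p.arch, TranscrDegrArch) else Kind.PROTEIN
            downstream[(p.arch.downstream_id, kind, cond)] = traj

    def noise() -> float:
        if spec.noise_sigma == 0:
            return 1.0
        s = spec.noise_sigma
        return float(rng_noise.lognormal(mean=-0.5 * s * s, sigma=s))

    recordings: list[RawRecording] = []
    actin_base = 1000.0

    def record(mid: str, kind: Kind, cond: Condition, days, values) -> None:
        n_rep = spec.n_replicates.get(kind, 1)
        for day, val in zip(days, values):
            for rep in range(1, n_rep + 1):
                recordings.append(
                    RawRecording(mid, kind, cond, float(day), rep, float(val) * noise())
                )

    # actin lanes first so every protein lane has its control
    protein_ids = sorted(proteins) + sorted(
        {p.arch.downstream_id for p in spec.planted if isinstance(p.arch, TranslInhibArch)}
    )
    actin_lanes: dict[tuple[Condition, float, int], float] = {}
    if protein_ids:
        n_rep = spec.n_replicates.get(Kind.PROTEIN, 1)
        for cond in (Condition.WT, Condition.KO):
            for day in PROTEIN_DAYS:
                for rep in range(1, n_rep + 1):
                    lane = actin_base * noise()
                    actin_lanes[(cond, day, rep)] = lane
                    recordings.append(
                        RawRecording("actin", Kind.PROTEIN, cond, day, rep, lane)
                    )

    for cond in (Condition.WT, Condition.KO):
        for mid in sorted(templates):
            tpl = templates[mid]
            if (mid, tpl.kind, cond) in downstream:
                continue  # simulated below, not from the template
            vals = tpl.values[cond]
            if tpl.kind is Kind.PROTEIN:
                n_rep = spec.n_replicates.get(Kind.PROTEIN, 1)
                for day, val in zip(tpl.days, vals):
                    for rep in range(1, n_rep + 1):
                        raw = val * actin_lanes[(cond, day, rep)] * noise()
                        recordings.append(RawRecording(mid, tpl.kind, cond, day, rep, raw))
            else:
                record(mid, tpl.kind, cond, tpl.days, vals)

        for (mid, kind, dcond), traj in sorted(downstream.items()):
            if dcond is not cond:
                continue
            days = MRNA_DAYS if kind is Kind.MRNA else PROTEIN_DAYS
            vals = _sample_days(traj, grid, days)
            if kind is Kind.PROTEIN:
                n_rep = spec.n_replicates.get(Kind.PROTEIN, 1)
                for day, val in zip(days, vals):
                    for rep in range(1, n_rep + 1):
                        raw = val * actin_lanes[(cond, day, rep)] * noise()
                        recordings.append(RawRecording(mid, kind, cond, day, rep, raw))
            else:
                record(mid, kind, cond, days, vals)

    pairs = {pair for p in spec.planted for pair in p.arch.pairs}
    pairs.update(spec.decoy_pairs)
    table = TargetTable.from_pairs(sorted(pairs))

    tf_genes: dict[str, GeneTFSpec] = {}
    for p in spec.planted:
        if isinstance(p.arch, TranscrDegrArch):
            tf_genes[p.arch.gene] = GeneTFSpec(
                repressors=tuple(p.arch.rep_proteins),
                activators=tuple(p.arch.act_proteins),
                mode="fixed",
            )
    for gene in decoy_genes:
        tf_genes[gene] = GeneTFSpec(
            repressors=(spec.knockout_protein,) if proteins else (),
            activators=(),
            mode="fixed",
        )
    return SimOutput(
        recordings=tuple(recordings),
        target_table=table,
        truth=tuple(spec.planted),
        tf_config=TFConfig(tf_genes),
    )


def default_recovery_spec(seed: int = 0, noise_sigma: float = 0.05) -> SimSpec:
    """A small campaign with one planted interaction of each kind and three
    decoy pairs; the planted parameters lie inside the fitter's search space.

    The TD interaction degrades gene ``tdgene`` via the HL miRNA mir-001
    under GCNF repression and Oct4 activation; the TI interaction represses
    protein ``tigene`` via the LH miRNA mir-006 (strong late repression, so
    the protein's late decline identifies its decay rate).
    """
    td_arch = TranscrDegrArch(
        gene="tdgene",
        mirnas=("mir-001",),
        rep_proteins=("GCNF",),
        act_proteins=("Oct4",),
    )
    td_params = TDParams(
        hill={"GCNF": HillParams(c=1, gamma=1.5), "Oct4": HillParams(c=1, gamma=2.0)},
        k_transcr=400.0,
        k_react=3e-4,
        k_deg=0.35,
    )
    ti_arch = TranslInhibArch(gene="tigene", protein="tigene", mirnas=("mir-006",))
    ti_params = TIParams(
        hill={"mir-006": HillParams(c=1, gamma=1.2e-3)},
        k_transl=2e-3,
        k_degP=0.35,
    )
    planted = (
        PlantedInteraction(td_arch, td_params),
        PlantedInteraction(ti_arch, ti_params),
    )
    decoys = (("mir-002", "decoyA"), ("mir-007", "decoyB"), ("mir-010", "decoyC"))
    return SimSpec(
        seed=seed,
        n_mirnas=10,
        class_mix=DEFAULT_CLASS_MIX,
        noise_sigma=noise_sigma,
        planted=planted,
        decoy_pairs=decoys,
    )


def _planted_from_dict(d: dict) -> PlantedInteraction:
    hill = {k: HillParams(c=int(v["c"]), gamma=float(v["gamma"])) for k, v in d.get("hill", {}).items()}
    rates = d.get("rates", {})
    if d["kind"] == "TD":
        arch = TranscrDegrArch(
            gene=d["gene"],
            mirnas=tuple(d["mirnas"]),
            rep_proteins=tuple(d.get("repressors", [])),
            act_proteins=tuple(d.get("activators", [])),
        )
        params = TDParams(
            hill=hill,
            k_transcr=float(rates["k_transcr"]),
            k_react=float(rates["k_react"]),
            k_deg=float(rates["k_deg"]),
        )
    elif d["kind"] == "TI":
        arch = TranslInhibArch(
            gene=d["gene"], protein=d.get("protein", d["gene"]), mirnas=tuple(d["mirnas"])
        )
        params = TIParams(
            hill=hill,
            k_transl=float(rates["k_transl"]),
            k_degP=float(rates["k_degP"]),
            k_degP_ko=float(rates["k_degP_ko"]) if "k_degP_ko" in rates else None,
        )
    else:
        raise SimSpecError(f"unknown planted kind {d.get('kind')!r}")
    initial = None
    if d.get("initial") not in (None, "equilibrium"):
        initial = {Condition(c): float(v) for c, v in d["initial"].items()}
    return PlantedInteraction(arch, params, initial)


def spec_from_yaml(path) -> SimSpec:
    """Load a campaign specification from a flat YAML file."""
    import yaml
    from pathlib import Path

    raw = yaml.safe_load(Path(path).read_text()) or {}
    kwargs: dict = {}
    for key in ("seed", "n_mirnas", "noise_sigma", "knockout_protein"):
        if key in raw:
            kwargs[key] = raw[key]
    if "class_mix" in raw:
        kwargs["class_mix"] = tuple(raw["class_mix"])
    if "n_replicates" in raw:
        kwargs["n_replicates"] = {Kind(k): int(v) for k, v in raw["n_replicates"].items()}
    if "planted" in raw:
        kwargs["planted"] = tuple(_planted_from_dict(d) for d in raw["planted"])
    if "decoy_pairs" in raw:
        kwargs["decoy_pairs"] = tuple((m, g) for m, g in raw["decoy_pairs"])
    return SimSpec(**kwargs)


def truth_to_yaml(truth: Sequence[PlantedInteraction], path) -> None:
    """Serialize the planted ground truth alongside the simulated data."""
    import yaml
    from pathlib import Path

    entries = []
    for p in truth:
        if isinstance(p.arch, TranscrDegrArch):
            rates = {"k_transcr": p.params.k_transcr, "k_react": p.params.k_react, "k_deg": p.params.k_deg}
            entry = {
                "kind": "TD",
                "gene": p.arch.gene,
                "mirnas": list(p.arch.mirnas),
                "repressors": list(p.arch.rep_proteins),
                "activators": list(p.arch.act_proteins),
            }
        else:
            rates = {"k_transl": p.params.k_transl, "k_degP": p.params.k_degP}
            if p.params.k_degP_ko is not None:
                rates["k_degP_ko"] = p.params.k_degP_ko
            entry = {"kind": "TI", "gene": p.arch.gene, "protein": p.arch.protein, "mirnas": list(p.arch.mirnas)}
        entry["rates"] = rates
        entry["hill"] = {k: {"c": hp.c, "gamma": hp.gamma} for k, hp in p.params.hill.items()}
        entry["initial"] = (
            "equilibrium" if p.initial is None else {c.value: v for c, v in p.initial.items()}
        )
        entries.append(entry)
    Path(path).write_text(yaml.safe_dump({"planted": entries}, sort_keys=False))


def recovery_fixture(spec: SimSpec) -> tuple[SimOutput, dict[tuple[str, str], bool]]:
    """Simulated campaign plus the ground-truth pair verdicts: every planted
    (miRNA, gene) pair true, every decoy pair false."""
    out = simulate_downstream(spec)
    expected: dict[tuple[str, str], bool] = {}
    for m, g in spec.decoy_pairs:
        expected[(m, g)] = False
    for p in spec.planted:
        for pair in p.arch.pairs:
            expected[pair] = True
    return out, expected
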