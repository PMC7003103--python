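"""Serial-batch pooled-competition simulator with a measurement model.

The simulator reproduces the statistical structure of a bar-seq competitive
fitness experiment: a pool of barcoded strains grown through repeated
grow-then-dilute passages (~8 generations each, sampled T1-T4), a
strain-specific DNA-extraction bias spanning >20-fold, multinomial
sequencing at 1e3-1e5 counts per strain, and FASTQ emission of the
150-bp bipartite barcode amplicon.

Fitness convention: the selection coefficient s_i is a log2 per-generation
growth-rate advantage, so a strain's log2 abundance ratio changes by
s_i * dg over dg generations of competitive growth.  Within one growth
phase of g_p generations a strain's abundance multiplies by
2**((1 + s_i) * g_p) before renormalization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .barcodes import AmpliconTemplate, BarcodeLibrary, BASES, make_barcode_library
from .counting import CountMatrix

_TIMEPOINTS = ("T1", "T2", "T3", "T4")


@dataclass(frozen=True)
class StrainGenotype:
    """One barcoded strain: identity, barcode pair, measurement bias.

    extraction_bias is the positive multiplier b_i distorting the strain's
    template share during DNA extraction; it is a fixed property of the
    strain, identical across all samples of an experiment.
    """

    strain_id: str
    barcode_up: str
    barcode_dn: str
    extraction_bias: float = 1.0
    initial_fraction: float = 0.0

    def __post_init__(self) -> None:
        for code in (self.barcode_up, self.barcode_dn):
            if len(code) != 12 or any(c not in BASES for c in code):
                raise ValueError(
                    f"strain {self.strain_id!r}: invalid 12-nt barcode {code!r}"
                )
        if not self.extraction_bias > 0:
            raise ValueError(
                f"strain {self.strain_id!r}: extraction_bias must be > 0"
            )
        if not 0.0 <= self.initial_fraction <= 1.0:
            raise ValueError(
                f"strain {self.strain_id!r}: initial_fraction outside [0, 1]"
            )


@dataclass
class FitnessMap:
    """Per-(condition, strain) selection coefficients.

    s = 0 encodes neutrality.  Backed by a strains x conditions DataFrame.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if not np.isfinite(self.table.to_numpy(dtype=float)).all():
            raise ValueError("selection coefficients must be finite")

    @classmethod
    def neutral(cls, strain_ids: list[str], conditions: list[str]) -> "FitnessMap":
        return cls(pd.DataFrame(0.0, index=list(strain_ids), columns=list(conditions)))

    def s(self, condition: str, strain_ids: list[str]) -> np.ndarray:
        if condition not in self.table.columns:
            raise KeyError(f"no fitness entries for condition {condition!r}")
        missing = [s for s in strain_ids if s not in self.table.index]
        if missing:
            raise KeyError(f"no fitness entries for strains {missing}")
        return self.table.loc[list(strain_ids), condition].to_numpy(dtype=float)


@dataclass(frozen=True)
class SerialBatchDesign:
    """Parameters of a serial-batch competition experiment.

    Defaults follow the assay design: four sampled growth phases (T1-T4),
    ~8 generations per passage so that T1->T3 spans ~16 generations, a 1:100
    transfer dilution, and triplicate cultures per condition.
    ``bottleneck_cells=None`` means a deterministic (infinite-bottleneck)
    transfer with no drift.
    """

    conditions: tuple[str, ...] = ("control", "treatment")
    reference: str = "control"
    n_passages: int = 4
    generations_per_passage: float = 8.0
    transfer_dilution: float = 0.01
    bottleneck_cells: int | None = 1_000_000
    replicates: int = 3
    depth: int = 30_000
    read_error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.reference not in self.conditions:
            raise ValueError(f"reference {self.reference!r} not in conditions")
        if self.generations_per_passage <= 0:
            raise ValueError("generations_per_passage must be positive")
        if not 0.0 < self.transfer_dilution < 1.0:
            raise ValueError("transfer_dilution must lie in (0, 1)")
        if self.n_passages < 1:
            raise ValueError("n_passages must be >= 1")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.bottleneck_cells is not None and self.bottleneck_cells < 1:
            raise ValueError("bottleneck_cells must be >= 1 or None")

    @property
    def timepoints(self) -> tuple[str, ...]:
        return _TIMEPOINTS[: self.n_passages]


def make_strain_pool(
    library: BarcodeLibrary,
    bias_fold_range: float = 22.0,
    seed: int = 0,
) -> list[StrainGenotype]:
    """Equal-fraction pool with log-normal extraction biases.

    Biases are log-normal across strains, rescaled so that max/min equals
    ``bias_fold_range`` exactly (default 22x, the observed spread of counts
    at near-equal abundance).  ``bias_fold_range=1`` gives unit biases.
    """
    if bias_fold_range < 1:
        raise ValueError("bias_fold_range must be >= 1")
    n = len(library)
    rng = np.random.default_rng(seed)
    if n == 1 or bias_fold_range == 1.0:
        biases = np.ones(n)
    else:
        z = rng.standard_normal(n)
        z = (z - z.min()) / (z.max() - z.min())  # [0, 1]
        biases = np.exp(z * np.log(bias_fold_range))
    frac = 1.0 / n
    return [
        StrainGenotype(sid, up, dn, extraction_bias=float(b), initial_fraction=frac)
        for (sid, (up, dn)), b in zip(library.pairs.items(), biases)
    ]


def _grow(fractions: np.ndarray, s: np.ndarray, generations: float) -> np.ndarray:
    """One competitive growth phase: x_i *= 2**((1+s_i)*g), renormalized."""
    with np.errstate(over="raise"):
        x = fractions * np.exp2((1.0 + s) * generations)
    total = x.sum()
    if total <= 0:
        raise RuntimeError("entire pool went extinct during growth")
    return x / total


def _bottleneck(
    fractions: np.ndarray, n_cells: int | None, rng: np.random.Generator
) -> np.ndarray:
    if n_cells is None:
        return fractions
    draw = rng.multinomial(n_cells, fractions)
    return draw / n_cells


def simulate_serial_batch(
    design: SerialBatchDesign,
    strains: list[StrainGenotype],
    fitness: FitnessMap,
) -> dict[tuple[str, int, str], np.ndarray]:
    """True strain cell fractions for every (condition, replicate, timepoint).

    Each growth phase multiplies strain abundance by 2**((1+s_i)*g_p) and
    renormalizes; fractions are sampled after every phase (T1, T2, ...).
    Transfers between phases draw ``bottleneck_cells`` cells multinomially
    (genetic drift); with ``bottleneck_cells=None`` the transfer is
    deterministic.  Replicates diverge only through drift.  Extinct lineages
    (fraction exactly 0) are legal.  Deterministic given ``design.seed``.
    """
    ids = [g.strain_id for g in strains]
    f0 = np.array([g.initial_fraction for g in strains], dtype=float)
    if abs(f0.sum() - 1.0) > 1e-9:
        raise ValueError(f"initial fractions sum to {f0.sum():.12f}, not 1")
    out: dict[tuple[str, int, str], np.ndarray] = {}
    ss = np.random.SeedSequence(design.seed)
    streams = ss.spawn(len(design.conditions) * design.replicates)
    k = 0
    for cond in design.conditions:
        s = fitness.s(cond, ids)
        for rep in range(1, design.replicates + 1):
            rng = np.random.default_rng(streams[k])
            k += 1
            frac = f0.copy()
            for p, tp in enumerate(design.timepoints):
                frac = _grow(frac, s, design.generations_per_passage)
                out[(cond, rep, tp)] = frac.copy()
                if p < design.n_passages - 1:
                    frac = _bottleneck(frac, design.bottleneck_cells, rng)
    return out


def apply_measurement_model(
    fractions: np.ndarray,
    strains: list[StrainGenotype],
    depth: int,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Observed barcode counts: multinomial(depth, p) with p_i ∝ f_i * b_i.

    b_i is the strain's extraction bias; biased template shares are
    renormalized before sampling.
    """
    fractions = np.asarray(fractions, dtype=float)
    if len(fractions) != len(strains):
        raise ValueError("fractions and strains length mismatch")
    if abs(fractions.sum() - 1.0) > 1e-6:
        raise ValueError("fractions must sum to 1")
    if depth < 0:
        raise ValueError("depth must be >= 0")
    bias = np.array([g.extraction_bias for g in strains], dtype=float)
    if not (bias > 0).all():
        raise ValueError("all extraction biases must be > 0")
    p = fractions * bias
    p = p / p.sum()
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    return rng.multinomial(int(depth), p)


def _mutate_reads(
    reads: np.ndarray, error_rate: float, rng: np.random.Generator
) -> np.ndarray:
    """Apply i.i.d. substitutions to a (n_reads, read_length) base-index array."""
    if error_rate == 0:
        return reads
    hit = rng.random(reads.shape) < error_rate
    # shift by 1-3 positions in base space: always a *different* base
    shift = rng.integers(1, 4, size=reads.shape)
    return np.where(hit, (reads + shift) % 4, reads)


def emit_fastq(
    counts: dict[str, int],
    library: BarcodeLibrary,
    template: AmpliconTemplate | None = None,
    error_rate: float = 0.0,
    seed: int | np.random.Generator = 0,
    sample_id: str = "sample",
    handle=None,
) -> list[str] | None:
    """Emit single-end FASTQ reads for the given per-strain counts.

    Each read is ``flank_up + barcode_up + spacer + barcode_dn`` padded with
    downstream flank context to ``template.read_length``, with i.i.d.
    substitutions at ``error_rate``.  Read order is shuffled.  Headers carry
    the sample identity in Illumina dual-index style
    (``@<sample>:<n> 1:N:0:<sample>``).  Qualities are constant Phred+33 'I'.

    Writes to ``handle`` if given, else returns the lines as a list.
    """
    if template is None:
        template = AmpliconTemplate()
    unknown = [sid for sid in counts if sid not in library]
    if unknown:
        raise KeyError(f"counts reference strains not in library: {unknown}")
    if not 0.0 <= error_rate < 1.0:
        raise ValueError("error_rate must lie in [0, 1)")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    base_idx = {b: i for i, b in enumerate(BASES)}

    def encode(seq: str) -> np.ndarray:
        return np.array([base_idx[c] for c in seq], dtype=np.int8)

    pad_needed = template.read_length - template.span
    pad = (template.flank_dn * (pad_needed // max(1, len(template.flank_dn)) + 1))[
        :pad_needed
    ] if pad_needed else ""
    templates = {}
    for sid, n in counts.items():
        if n < 0:
            raise ValueError(f"negative count for strain {sid!r}")
        up, dn = library.pairs[sid]
        templates[sid] = encode(template.flank_up + up + template.spacer + dn + pad)

    order = np.repeat(
        np.arange(len(counts)), [counts[s] for s in counts]
    )
    rng.shuffle(order)
    sids = list(counts)
    reads = np.stack([templates[sids[i]] for i in order]) if len(order) else np.empty(
        (0, template.read_length), dtype=np.int8
    )
    reads = _mutate_reads(reads, error_rate, rng)
    bases = np.array(list(BASES))
    qual = "I" * template.read_length
    lines: list[str] = []
    for n, row in enumerate(reads, start=1):
        seq = "".join(bases[row])
        lines.append(f"@{sample_id}:{n} 1:N:0:{sample_id}")
        lines.append(seq)
        lines.append("+")
        lines.append(qual)
    if handle is not None:
        handle.write("\n".join(lines) + ("\n" if lines else ""))
        return None
    return lines


@dataclass
class SimulatedExperiment:
    """Ground truth and observables of one simulated experiment."""

    design: SerialBatchDesign
    strains: list[StrainGenotype]
    fitness: FitnessMap
    library: BarcodeLibrary
    fractions: dict[tuple[str, int, str], np.ndarray]
    counts: CountMatrix
    sample_sheet: pd.DataFrame

    def truth_frame(self) -> pd.DataFrame:
        """True fractions as a tidy table (strain, condition, replicate, time)."""
        rows = []
        ids = [g.strain_id for g in self.strains]
        for (cond, rep, tp), frac in self.fractions.items():
            for sid, f in zip(ids, frac):
                rows.append((sid, cond, rep, tp, f))
        return pd.DataFrame(
            rows, columns=["strain_id", "condition", "replicate", "timepoint", "fraction"]
        )


def write_experiment(
    exp: "SimulatedExperiment",
    outdir,
    fastq: bool = False,
) -> None:
    """Write an experiment's observables and ground truth as plain text.

    Emits counts.tsv, sample_sheet.tsv, barcode_library.tsv, truth tables
    (true fractions, selection coefficients, extraction biases), a flat
    key=value scenario config, and optionally per-sample FASTQ files.
    """
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    exp.counts.to_tsv(outdir / "counts.tsv")
    exp.sample_sheet.to_csv(outdir / "sample_sheet.tsv", sep="\t", index=False)
    exp.library.to_tsv(outdir / "barcode_library.tsv")
    exp.truth_frame().to_csv(outdir / "true_fractions.tsv", sep="\t", index=False)
    exp.fitness.table.rename_axis("strain_id").to_csv(
        outdir / "true_selection.tsv", sep="\t"
    )
    pd.DataFrame(
        {
            "strain_id": [g.strain_id for g in exp.strains],
            "extraction_bias": [g.extraction_bias for g in exp.strains],
            "initial_fraction": [g.initial_fraction for g in exp.strains],
        }
    ).to_csv(outdir / "true_biases.tsv", sep="\t", index=False)
    d = exp.design
    with open(outdir / "scenario.cfg", "w") as fh:
        for key, val in [
            ("conditions", ",".join(d.conditions)),
            ("reference", d.reference),
            ("n_passages", d.n_passages),
            ("generations_per_passage", d.generations_per_passage),
            ("transfer_dilution", d.transfer_dilution),
            ("bottleneck_cells", d.bottleneck_cells),
            ("replicates", d.replicates),
            ("depth", d.depth),
            ("read_error_rate", d.read_error_rate),
            ("seed", d.seed),
        ]:
            fh.write(f"{key}={val}\n")
    if fastq:
        fq_rng = np.random.default_rng(np.random.SeedSequence((d.seed, 40_127)))
        for sample in exp.counts.samples:
            counts = exp.counts.counts[sample]
            with open(outdir / f"{sample}.fastq", "w") as fh:
                emit_fastq(
                    counts[counts > 0].to_dict(),
                    exp.library,
                    error_rate=d.read_error_rate,
                    seed=fq_rng,
                    sample_id=sample,
                    handle=fh,
                )


def simulate_experiment(
    design: SerialBatchDesign,
    strains: list[StrainGenotype] | None = None,
    fitness: FitnessMap | None = None,
    library: BarcodeLibrary | None = None,
    n_strains: int = 87,
    bias_fold_range: float = 22.0,
    batch: str = "L1",
) -> SimulatedExperiment:
    """Run the full generative pipeline down to a count matrix.

    Builds (or accepts) a barcode library and strain pool, simulates the
    serial-batch competition, applies the extraction-bias + multinomial
    measurement model at ``design.depth`` expected counts per sample, and
    assembles a CountMatrix plus a sample sheet (sample, treatment, time,
    replicate, batch).  All randomness derives from ``design.seed``.
    """
    if library is None:
        library = make_barcode_library(n_strains, min_distance=3, seed=design.seed)
    if strains is None:
        strains = make_strain_pool(
            library, bias_fold_range=bias_fold_range, seed=design.seed + 1
        )
    if fitness is None:
        fitness = FitnessMap.neutral(
            [g.strain_id for g in strains], list(design.conditions)
        )
    fractions = simulate_serial_batch(design, strains, fitness)
    ids = [g.strain_id for g in strains]
    meas_rng = np.random.default_rng(
        np.random.SeedSequence((design.seed, 9173))
    )
    cols: dict[str, np.ndarray] = {}
    sheet_rows = []
    for cond in design.conditions:
        for tp in design.timepoints:
            for rep in range(1, design.replicates + 1):
                name = f"{cond}_{tp}_r{rep}"
                cols[name] = apply_measurement_model(
                    fractions[(cond, rep, tp)], strains, design.depth, meas_rng
                )
                sheet_rows.append((name, cond, tp, rep, batch))
    counts = pd.DataFrame(cols, index=ids)
    sheet = pd.DataFrame(
        sheet_rows, columns=["sample", "treatment", "time", "replicate", "batch"]
    )
    cm = CountMatrix(
        counts,
        unassigned=pd.Series(0, index=counts.columns),
        ambiguous=pd.Series(0, index=counts.columns),
    )
    return SimulatedExperiment(
        design=design,
        strains=strains,
        fitness=fitness,
        library=library,
        fractions=fractions,
        counts=cm,
        sample_sheet=sheet,
    )
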