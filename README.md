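# m6ascope

Analysis toolkit for microscopy-based, amplification-free quantification of
N⁶-methyladenosine (m⁶A) on single mRNA molecules from single cells.

## The problem

In the underlying assay, polyA⁺ mRNA from cells lysed in subnanoliter
nanowells is captured on an oligo-dT coverslip, end-labeled with Cy3, and
m⁶A-modified molecules are immunolabeled in a second colour. TIRF imaging
resolves individual molecules as diffraction-limited spots, so the m⁶A
level of a cell is simply

    m6a_level = N(m6A⁺ molecules) / N(polyA⁺ molecules)

counted in that cell's well, and the per-gene level (after sequential FISH
decoding of gene identity) is the fraction of modified gene-specific
transcripts, reported only when the gene has ≥ 10 transcripts or a log-mean
expression ≥ 0.02. Linking those molecular counts back to cell phenotypes
requires registering two instruments' coordinate systems: the
low-magnification nanowell scan (a cell occupancy matrix, **COM**, default
121 × 381 wells) and the high-magnification flow-cell scan (an RNA density
matrix, **RDM**, default 31 × 51 fields of view). The RDM is slid over the
COM and the placement with the outlier Pearson correlation (z ≥ 5 against
the full offset distribution) registers each field of view to its well;
wells holding exactly one cell are then linked to their molecule counts.

`m6ascope` implements the complete computational chain:

- **`simulate`** — a forward simulator for the whole experiment: IVT control
  transcripts with fractional m⁶ATP incorporation, pixel-integrated Gaussian
  PSF rendering with Poisson + read noise, nanowell scans, fiducial beads and
  seqFISH rounds, all with recorded ground truth.
- **`spots`** — rolling-ball background subtraction (radius 3 px), Gaussian
  blur (σ = 1.1), local-maxima detection and isotropic 2D Gaussian fitting
  for sub-pixel localization.
- **`colocalize`** — one-to-one greedy spot matching (1 px radius for
  modification calling, 2 px for antibody validation), detection-rate /
  sensitivity / specificity metrics, and bead-based phase-cross-correlation
  alignment of imaging rounds.
- **`registration`** — cell detection and phenotype gating on the nanowell
  scan, COM/RDM construction, exhaustive 2D correlation registration, and
  singlet-well linking.
- **`quantify`** — single-cell and per-gene m⁶A levels, one-gene-per-round
  seqFISH decoding, expression normalization (per-cell totals → log₂ →
  gene centring), t-SNE embedding (perplexity 10) and housekeeping-gene QC.
- **`probes`** — deterministic seqFISH probe design: 25–30 nt windows,
  GC ∈ [45, 70] %, no homopolymer ≥ 5, ≥ 2 nt spacing, 17-nt cross-
  hybridization exclusion, 55 %-GC trimming to ≤ 32 probes, readout
  screening against a reference transcriptome, and primary-oligo assembly
  (`target + "TA" + revcomp(readout)`).

## Worked example

Simulate a two-phenotype experiment (planted m⁶A fractions 0.30 and 0.15,
~250 and ~200 molecules per cell) and run the full pipeline:

```python
from m6ascope import PipelineConfig, run_pipeline
from m6ascope.simulate import Phenotype, SimulationConfig, simulate_experiment

sim = SimulationConfig(
    com_shape=(30, 45), rdm_shape=(8, 10), rdm_offset=(11, 17),
    fov_shape=(128, 128), fov_margin=6, min_spot_separation=5.0,
    cell_blob_sigma=1.6,
    phenotypes=(
        Phenotype("K562", {"green": 250.0, "red": 30.0},
                  mean_molecules=260, m6a_fraction=0.30),
        Phenotype("YAC1", {"green": 30.0, "red": 250.0},
                  mean_molecules=210, m6a_fraction=0.15),
    ),
)
exp = simulate_experiment(sim, seed=1)

cfg = PipelineConfig(
    com_shape=sim.com_shape, rdm_shape=sim.rdm_shape,
    phenotype_gates={"K562": {"green": (100, 1e9), "red": (0, 99)},
                     "YAC1": {"green": (0, 99), "red": (100, 1e9)}},
    min_housekeeping_detect=0,
)
res = run_pipeline(exp, cfg)

print(f"registration offset: {res.registration.offset} "
      f"(planted {exp.truth.rdm_offset}), "
      f"r = {res.registration.correlation:.3f}, z = {res.registration.z_score:.1f}")
print(f"linked singlet cells: {len(res.linked)}")
for name, grp in res.linked.groupby("phenotype"):
    print(f"  {name}: n = {len(grp)}, mean m6A level = {grp.m6a_level.mean():.3f}")
```

which prints:

```
registration offset: (11, 17) (planted (11, 17)), r = 0.693, z = 5.9
linked singlet cells: 37
  K562: n = 15, mean m6A level = 0.318
  YAC1: n = 18, mean m6A level = 0.157
  unassigned: n = 4, mean m6A level = 0.239
```

The registration lands on the planted offset, only singlet wells are
linked, and the per-phenotype mean m⁶A levels recover the planted fractions
(0.318 vs 0.30 and 0.157 vs 0.15). The `unassigned` group collects cells
whose gated intensities fall outside both phenotype gates — typically
unresolved doublets, which is why their level sits between the two.

A command-line interface mirrors the stages
(`m6ascope simulate | detect | register | quantify | design-probes |
run-all`); see `m6ascope --help`.

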