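# bindscape

Ensemble analysis of protein–protein binding modes from large replica sets
of association trajectories.

When two proteins can bind on more than one surface — as is typical for
complexes involving intrinsically disordered regions — no single structure
describes the interaction. What characterizes it instead is an *ensemble* of
bound configurations: which residues touch how often, where the mobile
partner accumulates around the fixed one, how many distinct binding modes
exist and how they are populated, how strongly each mode binds, and how fast
the encounter complex forms. `bindscape` implements this analysis stack for
two-protein systems simulated as many independent replicas:

- **contacts** — per-residue inter-protein contact frequencies (any-particle
  minimum distance, 7 Å cutoff), compared against per-residue reference
  perturbation profiles (e.g. NMR chemical-shift perturbations) via
  RMSE = √(Σᵢ(CGᵢ − REFᵢ)²/N) after max-normalizing both; first-contact
  (encounter) times with a replica bootstrap (10 000 resamples).
- **density** — 3D occupancy grids of the mobile partner around the aligned
  partner (0.5 Å voxels, normalized to bulk water 1.0 g/cm³), with
  high-relative-density regions and their 26-connected components counting
  distinct binding modes.
- **sketchmap** — each frame encoded as N inter-protein minimum distances
  between rigid structural elements (D₁…D_N), embedded in 2D by minimizing
  the sketch-map stress χ² = Σ_{i<j} wᵢwⱼ[F(R_ij) − f(r_ij)]² / Σ_{i<j} wᵢwⱼ
  with sigmoid transfer functions F, f; kernel-density clustering labels the
  *prime* (most populated) and *secondary* binding modes.
- **pmf** — the weighted histogram analysis method (WHAM) for umbrella-
  sampling data (0.5 Å windows, harmonic biases), Monte-Carlo bootstrap
  errors (100 trials), binding free energy ΔG = PMF(RC = 1.5 Å) −
  PMF(RC = 14.5 Å) with quadrature error, Welch t-tests between ΔG sets,
  and detection of "gliding" (contact turnover during enforced dissociation).
- **poses** — representative-pose selection (COM/RMSD pre-filters → high-
  density region membership → seeded random draw), pairwise pose RMSD
  matrices, and the refolding RMSD relative to the first-contact complex.
- **synthetic_data** — a two-body overdamped-Langevin binding simulator with
  planted binding sites of known depth and population, an optional flexible
  tail (IDR mimic, reproducing the fly-casting rate enhancement), and a
  Metropolis umbrella-window sampler for analytic 1D potentials. Every
  analysis above is verified against this generator's closed-form ground
  truth.

Trajectory I/O (PDB, DCD, XTC) is handled through MDAnalysis; all lengths
are Å, times ns, energies kcal/mol.

## Worked example

The `demo` subcommand runs the whole pipeline on the synthetic system
(20 replicas, 300 ns each, two planted binding sites with a 0.7/0.3
population split):

```sh
bindscape demo --out demo_out --seed 0
```

which prints (excerpt of `demo_out/summary.json`):

```json
{
  "contacts": {
    "encounter": {"mean_ns": 76.37, "sem_ns": 9.62, "n_replicas": 20, "n_no_contact": 2},
    "rmse_vs_reference": 0.129
  },
  "pmf": {
    "dG_kcal_mol": -1.991, "dG_error_kcal_mol": 0.148,
    "rc_bound": 1.45, "rc_unbound": 14.45
  },
  "sketchmap": {
    "modes": [{"label": "prime", "population": 0.8475},
              {"label": "secondary", "population": 0.1525}],
    "stress": 0.0073
  },
  "poses": {"selection_log": {"total": 6020, "geometry": 2074, "density": 148, "selected": 20}}
}
```

Reading this: the two proteins first touch after 76 ± 10 ns on average
(2 of 20 replicas never met within 300 ns and are reported, not averaged);
the simulated contact map deviates from the planted reference interface by
RMSE 0.13 on the [0, 1] scale; dissociating the demo complex along the
analytic double-well reaction coordinate costs 2.0 ± 0.1 kcal/mol; and the
embedded bound configurations split into a prime and a secondary mode. At
this short demo length the mode populations (0.85/0.15) are still drifting
toward the planted 0.70/0.30 equilibrium — the full-length conditions used
by the test suite recover 0.70/0.30 within ±0.05. Pose selection kept 2 074
of 6 020 frames after the geometric filters, 148 inside the high-density
region, and drew 20 representatives.

Per-stage artifacts land next to the summary: `contact_profile.csv`,
`occupancy.dx` (OpenDX, viewable in VMD/ChimeraX), `sketchmap.csv`,
`pmf.csv`, `poses.pdb`, plus `config.yaml` echoing every parameter and seed.

Real umbrella data can be analyzed directly from the plain-text window
format (one file per window with a `# center k` header, plus a
`metadata.txt` listing `file center k`):

```sh
bindscape wham path/to/metadata.txt --bin-width 0.1 --out pmf.csv
```

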