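# stdgem

Analysis toolkit for ligand-observed STD-NMR screening combined with
molecular modelling: group epitope mapping from saturation-transfer
difference intensities, protein–ligand interaction fingerprints from pose
coordinates, RMSD clustering of conformer ensembles, and concordance
scoring between the NMR epitope and the in-silico contact map.

## Who this is for

Structural biologists and medicinal chemists running STD-NMR screens
against a protein target (for instance an RNA-binding protein such as
HuR/ELAVL1, whose tandem RRM domains exchange between "open" and "closed"
conformations) who also have docking poses or MD snapshots and want a
reproducible, scriptable way to answer:

* which compounds of a panel bind, and through which protons (the
  *group epitope map*),
* which residues the poses say those compounds touch,
* whether the NMR epitope and the modelled contacts tell the same story,
  and which protein conformational state the NMR data supports.

## The quantities at the core

For every resolved ligand resonance with off-resonance (reference)
integral `I0` and on-resonance integral `Isat`, the **fractional STD
effect** is

```
f = (I0 − Isat) / I0          absolute STD % = 100 · f
```

Protons closest to the protein surface are saturated most, so ranking a
ligand's protons by STD delineates its binding epitope.  **Relative STD
%** rescales each compound so its most intense signal is exactly 100%,
conveyed by the conventional colour code (black = maximum, dark red
> 80%, orange > 40%, lime < 40%).  Absolute intensities are additionally
binned into the standard reporting ranges (>1, 1.0–0.9, …, <0.2 %), and
a compound with no signal above the noise floor (default 0.05%) is
called a non-binder.

On the modelling side, hydrogen bonds (D···A ≤ 3.5 Å, D–H···A ≥ 120°),
hydrophobic contacts (apolar C···C ≤ 4.5 Å) and cation-π interactions
(Arg/Lys cation ≤ 6.0 Å from an aromatic ring centroid, ≤ 45° off the
ring normal) are catalogued per residue and projected onto ligand
protons over a one-bond neighbourhood.  Conformer ensembles are
superposed pairwise (Kabsch), clustered with k-medoids on the RMSD
matrix (so representatives are actual frames; k = 10 by default), and
assigned to reference states by nearest superposed RMSD.  Per compound,
the agreement between absolute STD % and contact counts is a Spearman
rank correlation ρ; the protein state with the highest mean ρ across the
panel is the one the NMR data supports.

A synthetic-data generator emulates the screening conditions (1000:1
ligand excess — 400 µM ligand vs 0.4 µM protein — and a 2.94 s
saturation train) with a distance-dependent transfer model
`f ∝ Σ (r0/r)^6`, planted contacts, planted binder flags, and two-state
ensembles, so the whole pipeline is testable end to end without
experimental data.

## Worked example

```
$ python examples/01_quantify_epitope.py
compound demo: binder = True
 proton  abs STD %  rel STD %        class      bin
     H6       1.20      100.0          MAX       >1
     H8       1.00       83.3     DARK_RED  1.0-0.9
    H2'       0.50       41.7       ORANGE  0.6-0.5
    H3'       0.25       21.2         LIME  0.4-0.2
    4''       0.02        1.9  BELOW_FLOOR     <0.2
```

H6 loses 1.2% of its intensity under protein saturation — the largest
effect, so it anchors the relative scale (100%, black dot) and marks the
part of the ligand buried deepest in the site.  H8 at 83% is dark red;
the proton at 0.02% is below the 0.05% noise floor and carries no
epitope information.

```
$ python examples/04_concordance_panel.py
...
    cpd12    True   POCKET_INTERIOR         0.95   AGREE_BINDER
    cpd13   False  EXTERNAL_SURFACE            -   AGREE_NONBINDER

mean Spearman rho per state: closed: 0.902, open: -0.015
selected state: closed (margin 0.918)
```

Twelve of the thirteen simulated compounds are detected as binders with
pocket-interior poses; the planted non-binder shows no signal and an
external-surface pose.  The "closed" poses — generated consistently with
the simulated STD — reach mean ρ ≈ 0.9 while the shuffled "open" poses
are uncorrelated, so state selection picks "closed" by a wide margin.

The other examples cover contact fingerprints on a planted toy pocket
(`02`) and RMSD clustering of a two-state ensemble (`03`).

## Command line

A thin CLI wraps the library:

```
stdgem --show-config            # print every numeric default
stdgem simulate  --out-dir demo --seed 1
stdgem epitope   --peaks demo/panel/peaks.csv --out-dir demo/epitope
stdgem contacts  --pdb demo/panel/cpd01/pose_closed.pdb \
                 --topology demo/panel/cpd01/topology.csv
stdgem cluster   --pdb demo/panel/ensemble.pdb --k 2
stdgem concord   --profile run/profiles/cpd01.json --counts contacts/per_proton_counts.csv
stdgem run-all   --out-dir run --seed 1
```

`run-all` executes simulate → quantify → contacts → cluster → concord and
writes a `manifest.json` recording the resolved configuration, seed and
per-stage status.  Exit codes: 0 ok, 2 input error, 3 stage failure.
Parameters can also come from a YAML file (`--config`); flags override it.

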