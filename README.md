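# nucdamage

Tools for building DNA-damage constructs in nucleosome models and analysing
the recognition-relevant geometry of conformational ensembles.

The package covers the analysis side of a damage-recognition study:

* **Constructs** — uracil substitution on an idealized glycosidic frame,
  extrahelical base flipping about the flanking phosphate axis, and
  single-strand breaks (SSB) with 3'-OH / 5'-dRP termini and the
  5'-G\*G-3' / 3'-CTC-5' flank motif.
* **Nucleosome geometry** — superhelical axis fit, per-nucleotide
  superhelical location (SHL) with the dyad at 0, gyre labels, the ~14
  inward minor-groove contact points, and easy/medium/hard accessibility
  calls with histone-tail proximity.
* **Observables** — SSB gap distance *dg* (C3'–C3'), local twist Φ
  (dihedral over the flanking base-pair C3' atoms, ~60–70° in relaxed
  B-DNA), gyre gaping *dw*, probe/contact distances, H-bond series, and
  RMSD with optimal superposition. Distances in nm, angles in degrees.
* **Clustering** — GROMOS neighbor-counting on a dense pairwise-RMSD
  matrix (default cutoff 0.45 nm), deterministic tie-breaking.
* **Interface analysis** — Shrake–Rupley-style SASA, buried interface area
  ((SASA_a + SASA_b − SASA_ab)/2), and H-bond / salt-bridge / hydrophobic
  contact counts with per-site splits. Solvation free energies are not
  computed; the report schema keeps a field for imported values.
* **Synthetic data** — an ideal B-DNA builder, left-handed nucleosomal
  superhelix wrapper, and a seeded trajectory generator that drives dg, Φ,
  dw and probe distances along exact per-frame schedules (plus clipped
  Gaussian noise), with a ground-truth log for parameter-recovery testing.
  This replaces an MD engine for validation purposes.

## Library quick start

```python
import numpy as np
import nucdamage as nd

seq = "".join(np.random.default_rng(0).choice(list("ACGT"), 145))
wrap = nd.wrap_superhelix(nd.build_bdna(seq))          # 145-bp nucleosome mimic
smap = nd.shl_map(wrap, ("I", "J"))                    # SHL per nucleotide
print(len(nd.contact_points(smap, wrap)))              # -> 14

model, ssb = nd.make_ssb(wrap, ("I", 21))              # SSB near SHL -5
model = nd.set_flank_motif(model, ssb)                 # G*G / CTC motif
traj, truth = nd.make_trajectory(
    model, [nd.DeformationSignal("dg", np.linspace(1.2, 2.2, 100),
                                 noise_sigma=0.02, site=ssb)],
    seed=1, shlmap=smap)
dg = nd.gap_distance_series(traj, ssb)                 # nm, per frame
```

## Command line

A single entry point with one subcommand per stage:

```bash
nucdamage build-damage --in nuc.pdb --site I:34 --kind ssb \
    --five-cap drp --out damaged.pdb --site-json site.json
nucdamage analyze --traj traj.pdb --top damaged.pdb --site site.json \
    --obs dg,phi --out series.csv
nucdamage cluster --traj traj.pdb --top damaged.pdb --cutoff 0.45 \
    --out clusters.json --center-pdb best.pdb
nucdamage interface --pdb complex.pdb --a "chain A" --b "chain I,J" \
    --site I:46 --out report.json
nucdamage report --config run.yaml      # full pipeline from a YAML config
```

Binary trajectory formats (XTC/TRR/DCD) are consumed through an adapter
hook (`read_trajectory(..., format="adapter", adapter=frame_iterator)`);
the core only parses multi-model PDB.

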