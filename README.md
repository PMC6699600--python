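# porescope

Structural and functional annotation of ion-channel pores. Given a channel
structure (a PDB file; optionally a multi-model trajectory with waters),
porescope:

1. traces the **permeation pathway** by sweeping a spherical probe through a
   hard-sphere model of the protein, maximizing the probe radius in successive
   planes with the downhill simplex method;
2. interpolates the probe centers into an **arc-length-parameterized centerline
   spline** with a continuous pore-radius profile (and an optional extruded
   surface mesh);
3. maps particles into **curvilinear coordinates** (s, rho, phi) around the
   centerline — a generalization of cylindrical coordinates for curved pores;
4. estimates the **water density** along the pathway by Gaussian kernel density
   estimation, converts it to a number density via the local pore cross
   section, and **Boltzmann-inverts** it into a free-energy profile with
   de-wetted regions flagged;
5. classifies **pore-lining and pore-facing residues** and computes a
   kernel-smoothed **hydrophobicity profile** from normalized hydrophobicity
   scales (Wimley-White interface by default; octanol, Kyte-Doolittle and
   Hessa scales bundled) — together, the ingredients needed to detect
   hydrophobic gates that radius profiles alone miss.

For trajectories every frame is analyzed independently and profiles are
aggregated into mean / standard deviation / min / max bands plus a water
density heatmap (frames x position).

All internal lengths are nm; energies are kJ/mol.

## Command-line usage

```sh
# generate a synthetic hourglass pore with waters (no downloads needed)
porescope fixtures make --shape hourglass --waters 5000 -o pore.pdb

# full annotation: radius, hydrophobicity, density, free energy, de-wetting
porescope run -f pore.pdb --mode full --out results_dir --mesh

# geometry only (no waters required)
porescope run -f structure.pdb --mode geometry --out results_dir
```

Key options: `--probe-step` (nm, default 0.1), `--stop-radius` (default 1.0),
`--simplex-iter` (default 100), `--init-point x,y,z`, `--direction x,y,z`,
`--bandwidth <nm|amise>` (default 0.14), `--temperature`,
`--hydrophobicity-scale <name|file>`, `--pf-cutoff` (default 0.75 nm),
`--smoothing-span` (default 0.225 nm), `--bulk-band lo,hi`,
`--dewet-fraction`, `--dewet-minlen`.

Outputs: `report.json` (all profiles with units, residue annotations,
de-wetted intervals, echoed config), `annotated.pdb` (pore-lining indicator in
the occupancy column, pore-facing in the B-factor column; time averages for
trajectories), `density_matrix.csv`, optional `pore_surface.obj`.

## Library usage

```python
import porescope as ps

frame = ps.assign_vdw_radii(ps.read_structure(open("pore.pdb").read())[0])
trace = ps.find_pathway(frame)                       # probe sweep
spline = ps.fit_centerline(trace)                    # unit-speed curve
radius = ps.radius_function(spline, trace)           # R(s) profile
residues = ps.classify_residues(frame, spline, radius,
                                scale=ps.load_scale("wimley-white-interface"))
hydro = ps.hydrophobicity_profile(residues, radius.s)
solvent = ps.analyze_solvent(frame, spline, radius)  # P(s), n(s), G(s)
```

Synthetic pores with analytic ground truth (cylinder, hourglass, funnel, bent)
and Boltzmann-consistent water placements are available from
`porescope.fixtures` — the whole test suite runs offline on these.

## Notes

- The bundled van der Waals radius table is the Bondi (1964) element set
  (`src/porescope/data/vdw_radii.tsv`); it can be replaced by any
  `VdwRadiusTable` with per-element or per-(residue, atom-name) entries.
- Hydrophobicity scales are plain two-column text files; custom scales can be
  passed by path. Normalization rescales to [-1, +1] (most hydrophilic to most
  hydrophobic) while preserving the natural zero.
- The centerline spline uses natural end conditions with chord-length
  parameterization, then arc-length reparameterization (Gauss-Legendre
  quadrature + monotone inverse); ring orientation for the surface mesh uses a
  rotation-minimizing frame.
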