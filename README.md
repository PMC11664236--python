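# beevision

Visual-trait morphometrics for bee compound eyes, and community-level
analysis of how those traits shift along a landscape tree-cover gradient.

The package covers the full computational chain:

1. **`beevision.eye_geometry`** — computes 11 visual traits from labelled 3D
   eye geometry (triangulated corneal mesh + facet-centre points): corneal
   surface area, facet number, mean facet diameter, local radius of
   curvature, inter-ommatidial (IO) angle, eye parameter, monocular field of
   view, binocular overlap, and the three ocellar traits (central/lateral
   lens diameters, alignment angle). Local optics are estimated per facet
   and averaged per ommatidium; the eye parameter is averaged as the local
   product `D_i * dphi_i`. Fields of view use an equal-area
   subdivided-icosahedron partition of the viewing sphere (5120 bins).
2. **`beevision.allometry`** — log-log scaling of traits against body size
   (inter-tegular distance), with optional phylogenetic GLS control from a
   Newick-derived Brownian correlation matrix; size-relative traits as
   back-transformed residual ratios; variance-ratio repeatability from a
   mixed model (species random intercept, body size fixed).
3. **`beevision.community`** — inventory aggregation over years, empty-site
   filtering, whole-vector resampling imputation of traits for unmeasured
   species (30 draws by default), community-weighted means (CWM), and
   species richness.
4. **`beevision.trait_environment`** — standardised-design models of
   log(CWM), per-species hurdle-Poisson abundance, and Poisson richness
   against tree cover plus covariates (log floral resource, latitude,
   longitude, elevation, lat x lon). Tree-cover effects are reported as the
   % change per +10 percentage points of tree cover.
5. **`beevision.synthetic_data`** — generators with analytic ground truth:
   spherical-cap facet lattices (known spacing, curvature, IO angle, eye
   parameter, cap area, field of view, closed-form binocular overlap),
   allometric trait tables, and hurdle-Poisson community surveys with a
   known induced CWM–tree-cover gradient. Every estimator in the package is
   validated against these oracles.
6. **`beevision.cli_io`** — CSV/PLY/Newick/JSON readers and writers with
   schema validation, YAML study configuration, and reproducibility
   manifests (input hashes, seeds, versions).

## Command line

```bash
# synthetic fixtures with analytic ground truth
beevision simulate-eye   --radius 1000 --spacing 20 --half-angle 60 --seed 1 --out eye/
beevision simulate-head  --separation 60 --seed 1 --out head/
beevision simulate-traits --n-species 20 --slope 0.66 --seed 1 --out traits/
beevision simulate-survey --n-sites 800 --n-species 12 --seed 1 --out survey/

# measurement and analysis
beevision traits --mesh-left eye/eye.ply --facets-left eye/facets.csv --itd 4.2 --out traits.csv
beevision allometry --traits species_traits.csv --phylo tree.nwk --out fits/
beevision repeatability --traits specimen_traits.csv --out repeatability.csv
beevision cwm --inventory inv.csv --traits species_traits.csv --n-draws 30 --seed 1 --out cwm.csv
beevision fit-env --cwm cwm.csv --env env.csv --out fits/
beevision run-all --config study.yaml
```

`study.yaml` names the inventory/environment/trait CSVs, output directory,
seed, number of imputation draws and number of common species to model; see
`tests/test_cli_io.py::TestCLI::test_run_all_from_config` for a worked
example.

## Data expectations

- Inventory: long CSV `site,species,year,count` (counts are non-negative
  integers, one record per site/species/year).
- Environment: CSV `site,tree_cover_pct,floral_resource_permille,lat,lon,elev_m`.
- Meshes: ASCII PLY; facet centres and ocelli: CSV with `id,x,y,z[,area]`.
- Phylogeny: Newick; converted to a Brownian-expectation correlation matrix.
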