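# facetsolv

Face-specific relative dissolution rates for faceted molecular crystals,
predicted from solid-state binding energies corrected for *inequivalent
wetting* by the dissolution medium.

Different (hkl) faces of a drug crystal dissolve at different rates, and
the classic assumption that the solution wets every face equally breaks
down badly for polar crystals in water.  `facetsolv` combines two
ingredients to predict the anisotropy:

1. **Solid-state binding energy** of each face — a distance-weighted
   lattice sum over the pair interactions between a central reference
   molecule M₀ and the molecules lying toward the face,

   *E*<sub>b</sub>(hkl) = Σ<sub>k</sub> *E*<sub>M₀Mₖ</sub> / *R*<sub>M₀Mₖ</sub>  (kcal·mol⁻¹·Å⁻¹),

   including pairs that stabilize the lattice by at least 0.01 kcal/mol.

2. **Surface wetting** from a grid-based rigid-probe scan: a solvent or
   solute probe molecule is translated over one reticular area
   (*S*<sub>hkl</sub> = *V*<sub>cell</sub>/*d*<sub>hkl</sub>) of an
   oriented 3×3×2 slab on planes 1 Å apart and rotated about its
   principal axes in 30° steps; every pose with a Dreiding-type
   interaction energy (12-6 van der Waals + 12-10 hydrogen bond +
   Coulomb) stronger than −2 kcal/mol is recorded.  Sorting the records
   from strongest to weakest gives a rank curve; a two-line intersection
   construction (best line through the steep head vs. least-squares line
   through the weak 5% tail) selects how many of the strongest
   interactions to average into the **surface interaction energy**
   *E*<sub>s</sub> of that (face, probe) pair.

Wetting enters the rate model through the **energy differential**

*E*<sub>d</sub> = *E*<sub>s</sub>(solvent)/MW<sub>solvent</sub> − *E*<sub>s</sub>(solute)/MW<sub>solute</sub>,

which modifies the normalized binding energy into *E*<sub>b,mod</sub>
together with face geometry (cell volume, reticular area, rugosity); the
relative dissolution rate of faces *i*, *j* is the ratio
*R*<sub>rel,D</sub> = *E*<sub>b,mod,i</sub>/*E*<sub>b,mod,j</sub>.

The package is aimed at crystal-engineering and pharmaceutical-materials
scientists who want a fast, force-field-level alternative to molecular
dynamics for ranking the dissolution propensity of crystal habit faces.

## Worked example

The model's arithmetic can be run directly from curated energies
("tables mode"), here for furosemide form I in water:

```python
from facetsolv import FaceModelInput, predict_dissolution

faces = [
    FaceModelInput("(10-1)", e_b=-0.38,
                   e_s={"furosemide": -5.77, "water": -5.89},
                   e_b_mod=0.128, experimental_rate=16.1),
    FaceModelInput("(010)", e_b=-0.03,
                   e_s={"furosemide": -6.91, "water": -5.06},
                   e_b_mod=0.147, experimental_rate=12.6),
    FaceModelInput("(001)", e_b=-0.01,
                   e_s={"furosemide": -5.76, "water": -4.08},
                   e_b_mod=0.026, experimental_rate=2.8),
]
pred = predict_dissolution(faces, solute="furosemide", solvent="water",
                           molar_masses={"furosemide": 330.74, "water": 18.02})
print(pred.faces[["e_d", "e_b_mod"]])
print(pred.ratios)
```

prints

```
             e_d  e_b_mod
face
(10-1) -0.309413    0.128
(010)  -0.259907    0.147
(001)  -0.209000    0.026
              predicted  experimental  discrepancy_pct
pair
(10-1)/(001)   4.923077          5.75        14.381271
(010)/(001)    5.653846          4.50        25.641026
```

Reading the output: the energy differential `e_d` is most negative for
(10-1) — water wets that face most strongly relative to the solute — and
the predicted rate ratio (10-1)/(001) ≈ 4.9 against the measured 5.75
(≈14% discrepancy), a dramatic improvement over the equivalent-wetting
model, which overpredicts this ratio by roughly a factor of five.

The full structure-in pipeline (CIF → oriented slab → grid scan → rank
analysis → model) is driven by a YAML config:

```bash
facetsolv fixtures --variant polar-pair -o toy    # materialize a toy crystal
facetsolv run config.yaml -o out                  # scan + analyze + predict
facetsolv predict tables.yaml -o out              # arithmetic only
```

Every run writes CSV/JSON artifacts plus a manifest with input checksums
so it can be re-run bit-identically.

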