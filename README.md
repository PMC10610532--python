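# leda-ms

Recognition and quantification of co-eluting isomers from ion-trap
LC-MS/MS data by **L**inear **E**quation of **D**econvolution
**A**nalysis — an overdetermined, non-negative linear unmixing of
product/reference ion abundance ratios.

## The problem

Positional isomers such as the caffeoylquinic acids (CQAs, [M−H]⁻ at
*m/z* 353) and dicaffeoylquinic acids (diCQAs, *m/z* 515) found in
*Acmella oleracea* extracts share a precursor ion and a common panel of
CID product ions, so neither MS nor MS/MS alone can tell them apart when
they co-elute. Full chromatographic separation works but is slow. The
alternative implemented here moves the specificity from the column to
the mass spectrometer: each isomer forms the common product ions with a
different, reproducible *yield*, and those yields are a fingerprint.

## The method

Within each chromatographic time segment the ion trap alternates two
MS/MS events on the shared precursor: a low-excitation event that leaves
the precursor intact (the **reference ion**, Ri) and a high-excitation
event that records the full product-ion spectrum (Pis). The excitation
amplitude (ExA) of the high-energy event is chosen from an
energy-resolved MS/MS (ERMS) study via the breakdown curves

- survival yield `SY = 100·P/(P + ΣPi)`,
- product-ion formation `PiF = 100·ΣPi/(P + ΣPi)` (`SY + PiF = 100`;
  the curves cross at 50%, at the compound-characteristic `SY_ExA50`),
- product-ion yield `PiY = 100·ΣPi/P_max`, whose maximum (`PiY_max`, at
  `ExA_max`) fixes the working amplitude; `P_max` is the precursor level
  on the pre-activation plateau.

For each isomer *x*, pure-compound runs give characteristic ratios
`(Pi/Ri)_x`. A measured ratio vector from a mixture is then modelled as

```
(Pi/Ri)_m = Σ_x (Pi/Ri)_x · f_x ,     f_x ≥ 0
```

one equation per product ion whose characteristic ratio reaches 2% for
at least one isomer. With more retained ions than isomers (4×3 for the
CQAs, 5×3 for the diCQAs with the shipped table) the system is
overdetermined and solved by non-negative least squares. Solved
scan-by-scan, the fractions `f_x` split the Ri chromatogram into one
reconstructed trace per isomer; solved on integrated areas they give
peak purity. Assigned Ri areas are converted to concentrations through
an external 5-CQA calibration curve (LOD/LOQ from 3.3·/10·
SE(intercept)/slope) and scaled to the extract by the dilution factor
(default ×20, i.e. 50 µL diluted to 1 mL).

## Worked example

Simulate the built-in six-isomer demo run (two time segments, 5% noise,
4-CQA hidden under a 13× larger co-eluting 5-CQA peak), then run the
scan-by-scan pipeline:

```sh
leda simulate --demo --seed 11 --out run.csv
leda pipeline --config pipeline.yaml --run run.csv --out results
```

where `pipeline.yaml` points at the bundled ratio tables and acquisition
segments, a calibration CSV and per-isomer integration windows (see
`tests/test_cli.py` for a complete config). The run above prints
`quantification: results/quantification.csv` containing:

```
isomer,ws_mg_l,ws_sd,es_mg_l,es_sd,ri_area,flags
3-CQA,0.7582955648754224,0.0,15.165911297508448,0.0,18957.389121885586,
5-CQA,5.282420482067161,0.0,105.64840964134322,0.0,132060.51205167905,
4-CQA,0.39403768451754717,0.0,7.880753690350943,0.0,9850.942112938706,
"3,4-diCQA",6.646343433085913,0.0,132.92686866171826,0.0,166158.58582714782,
"3,5-diCQA",17.082253231412732,0.0,341.64506462825466,0.0,427056.3307853183,
"4,5-diCQA",4.28191156381459,0.0,85.63823127629179,0.0,107047.78909536476,
```

`ws_mg_l` is the working-solution concentration from the calibration
curve, `es_mg_l` the extract concentration after the ×20 dilution
factor. The generator concentrations were 0.8, 5.5, 0.4, 7.0, 18.0 and
4.5 mg/L: every isomer — including the 4-CQA at 1/13 of its co-eluting
neighbour — is recovered within the simulated 5% noise, even though the
chromatogram never separates 5-CQA from 4-CQA. `results/` also holds one
reconstructed chromatogram per segment (time, Ri, per-isomer traces,
residual) and a log of the matrix dimensions and solver flags.

The same operations are available as a library:

```python
>>> import leda
>>> table = leda.load_bundled_ratio_table("CQAs")
>>> matrix = leda.assemble_leda_matrix(table, threshold=0.02)
>>> measured = 0.5*table.column("3-CQA") + 0.5*table.column("5-CQA")
>>> leda.solve_leda(matrix, measured).as_dict()
{'3-CQA': 0.5000000000000001, '5-CQA': 0.49999999999999994, '4-CQA': 4.7751363371694506e-17}
```

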