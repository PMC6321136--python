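# pharmfish

Ligand-based target fishing from multi-conformational 3-point pharmacophore
fingerprints.

The pipeline:

1. **pharmacophore** — 3D conformers are converted into typed potential
   pharmacophore points (donor, acceptor, positive, negative, aromatic,
   lipophilic; an atom may carry several types, aromatic points sit on ring
   centroids). All point triples within 20 Å are turned into canonical
   (type, binned opposite-edge distance) keys; the union over up to 10
   conformers is the compound's *modal fingerprint*.
2. **datasets** — labelled bioassay datasets with repeated stratified
   70/30 train/validation splits (≥30 repeats; every compound must appear
   in at least one validation set).
3. **ensemble** — one linear-SVM or Bernoulli naive-Bayes member per
   repeat. The SVM cost is picked from the 19-value grid 2⁻¹²…2⁶ by
   5-fold CV maximizing the Power Metric TPR/(TPR+FPR) at TPR+FPR = 0.5.
   Raw validation-set scores are pooled per compound (out-of-sample /
   "OOF" scores) and averaged.
4. **calibration** — a query's mean member score is converted into Pa
   (fraction of reference actives scoring worse) and Pi (fraction of
   reference inactives scoring better), ties counting ½. The member-score
   95% t-interval is propagated into Pa−Pi upper/lower limits; a compound
   is called active only if Pa−Pi ≥ threshold (default 0.15) **and** the
   lower limit is strictly positive (applicability-domain veto).
5. **metrics** — rank-sum AUC with midrank tie handling, its approximate
   standard error and Welch–Satterthwaite effective dof, ROC curves,
   F-score/MCC/enrichment-factor from contingency tables, threshold
   sweeps, and the strict AUC > 0.5 model filter.
6. **activity_classes** — bioassay models grouped into activity classes;
   class score = active (compound, model) instances / (n_compounds · √M),
   ranked per method and merged by (best rank, mean rank, class id).
7. **synthetic** — seeded planted-signal fingerprint generators, typed
   point clouds, and whole class collections for end-to-end recovery
   experiments.

## CLI

```sh
pharmfish simulate --out-dir sim --seed 7             # synthetic fixture
pharmfish fingerprint mols.sdf -o fps.tsv             # SDF -> modal fingerprints
pharmfish fingerprint mols.tsv --smiles -o fps.tsv    # SMILES + embedded conformers
pharmfish train --activity sim/activity.tsv --fingerprints sim/fingerprints.tsv \
    --method both --repeats 30 --seed 7 -o models/
pharmfish predict --model models/activity.svm_linear.model.json \
    --fingerprints fps.tsv --threshold 0.15 -o preds.tsv
pharmfish validate --model models/activity.svm_linear.model.json -o report.json
pharmfish validate --contingency TP=46,FP=21,TN=159,FN=79 \
    --prevalence 128/309 -o report.json
pharmfish rank-classes --predictions preds.tsv --class-map classes.tsv \
    --n-compounds 27 -o ranked.tsv
```

Every verb writes a `*.manifest.json` echoing its resolved configuration
and seeds so runs are reproducible; errors exit with categorized codes
(2 missing file, 3 structure, 4 schema, 5 degenerate data).

## File formats

All artifacts are plain TSV/JSON: activity tables
(`compound_id<TAB>label`), fingerprints (`compound_id<TAB>key1;key2;…`
with keys `T1T2T3:b1,b2,b3` or `#int` for synthetic bits), class maps
(`dataset_id<TAB>class_id`), prediction tables, ranked-class tables, and
JSON model bundles / validation reports.
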