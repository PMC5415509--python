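Packaged Pisione dataset
========================

Contents
--------
tree_combined.nwk    Rooted 26-terminal topology from the combined
                     (molecular + morphology) Bayesian analysis of the genus.
                     Topology only; no branch lengths.
matrix_table.csv     26 taxa x 44 unordered morphological characters.
                     States 0-3; '?' = unknown, '-' = inapplicable
                     (hierarchical "c-coding": dependent characters are
                     inapplicable where the controlling structure is absent).
characters_meta.csv  Character names, sexual vs non-reproductive class and
                     copulatory-group tags (AG/RG/CG/PG/GG = africana,
                     remota, crassa, papuensis, gopalai morphotype groups).
occurrences.csv      Decimal coordinates of the sequenced terminals
                     (16 records).  This is a small demonstration set, not
                     the full species-occurrence compilation of the genus.
traits_synthetic.csv Species-level continuous traits for the signal/PGLS
                     demonstrations.  The complexity column is computed from
                     the character matrix (count of state-1 cells among
                     characters 37-44); max_copulatory_organs,
                     max_body_length and max_segments are SYNTHETIC
                     stand-ins with field-plausible magnitudes, because the
                     real measurements are not tabulated anywhere in the
                     source dataset.  Do not use for biological inference.

Topology notes
--------------
* Within-species relationships (the three P. puzae terminals; the five
  P. hartmannschroederae terminals) are unresolved and stored as polytomies.
* The two P. guanche duplicates (Tenerife/Lanzarote) were removed a priori
  in the original analysis; the matrix holds exactly 26 terminals.
* The branching order among outgroup families is only partially resolved by
  the underlying analyses.  The packaged resolution places Pholoidae
  branching after Aphroditidae, then Polynoidae, then the remaining
  sigalionids: this is the resolution under which character 1 (palp
  surface) traces with homoplasy, matching the published tracing in which
  buccal aciculae (character 11) are the sole clean Pisione apomorphy.
  Synapomorphy detection for the three focal clades is insensitive to the
  remaining outgroup ambiguity (tested in the package's test suite).
* Locality suffixes distinguish conspecific terminals
  (e.g. Pisione_hartmannschroederae_Belize).  "cf." is written "cf".
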