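# Real PGS Catalog scoring files (not shipped)

`tests/test_acceptance.py::test_pgs_catalog_parse_counts` validates the
scoring-file parser against four published harmonized GRCh38 scoring files.
They are too large to commit and must be fetched over the network into this
directory first:

```sh
for acc in PGS004226 PGS000746 PGS002774 PGS004859; do
  curl -O "https://ftp.ebi.ac.uk/pub/databases/spot/pgs/scores/${acc}/ScoringFiles/Harmonized/${acc}_hmPOS_GRCh38.txt.gz"
done
```

Without these files the test fails with a message pointing here.
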