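# Published input tables (not redistributed)

Two acceptance tests reproduce published pooled numbers from the source
publication's supplementary tables. Those tables are not shipped here;
supply them as TSV in this directory to activate the checks:

- `observational_studies.tsv` — columns `label`, `outcome_group`
  (CAD/IS/ASCVD), `estimate` (OR/HR/RR), `ci_low`, `ci_high`, `design`
  (prospective/retrospective); one row per study estimate.
- `cannabis_exposure.tsv`, `outcome_cad.tsv`, `outcome_is.tsv` — standard
  summary-statistic columns `rsid`, `effect_allele`, `other_allele`,
  `eaf`, `beta`, `se`, `pvalue`, `n`; one row per instrument SNP.

Everything else in the package runs on synthetic data and needs nothing
from this directory.
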