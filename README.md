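# ethnokit

Quantitative ethnobotany toolkit: informant-consensus statistics, fidelity
levels, descriptive survey tabulations, and two-mode ailment–plant network
analysis over ethnomedicinal use-report data.

## The problem

Ethnomedicinal field surveys record *use reports* (use citations): one
informant stating that one plant species treats one ailment. From a table of
such reports, ethnobotanists quantify how strongly a community's knowledge
converges and which species anchor which treatments:

- **Informant consensus factor (ICF)** per ailment category:

  ICF = (n<sub>ur</sub> − n<sub>t</sub>) / (n<sub>ur</sub> − 1)

  where n<sub>ur</sub> is the number of use reports in the category and
  n<sub>t</sub> the number of distinct species cited for it. ICF = 1 when
  all informants converge on a single species; ICF = 0 when every citation
  names a different species.

- **Fidelity level (FL)** per (species, ailment) pair:

  FL = 100 × N<sub>p</sub> / N

  the share of a species' citations devoted to one specific ailment.
  FL = 100 means the species is used for a single ailment; a species' FL
  values partition its citations, so they sum to exactly 100.

- **Two-mode network analysis**: the ailment-category × species incidence
  matrix (entries = use-report counts) viewed as a weighted bipartite graph,
  with a one-mode category projection (edge weight = species shared between
  two categories' pharmacopoeias), UCINET DL interchange, a seeded
  force-directed layout, and reproducible grouping of categories by greedy
  modularity maximisation.

The package is shaped by the survey of 208 informants living around Gayasan
National Park (Korea) — 200 medicinal species, 16 Heinrich-style ailment
categories — whose published summary tables (per-category taxa/citation
counts, demographic ratios, per-species fidelity rows) are transcribed in
`ethnokit.datasets` as worked-example inputs. Because raw field data of such
surveys are rarely deposited, a seeded synthetic-survey generator
(`ethnokit.simulate`) with a Dirichlet–multinomial consensus model and an
exact ground-truth ledger makes every pipeline stage testable end to end.

## Worked example

ICF straight from published per-category counts:

```python
from ethnokit.datasets import category_counts_frame
from ethnokit.pipeline import icf_from_counts

table = icf_from_counts(category_counts_frame()[["category", "nt", "nur"]])
print(table.head(6).to_string(index=False))
```

```
                    category  nt  nur  icf_raw  icf_2dp
 Muscular-skeletal disorders  49 2142 0.977581     0.98
                       Pains  87 2942 0.970758     0.97
Respiratory system disorders  46 1513 0.970238     0.97
            Liver complaints  15  447 0.968610     0.97
             Cuts and wounds  20  473 0.959746     0.96
                Inflammation  28  587 0.953925     0.95
```

Reading: 2,142 citations across only 49 taxa for muscular-skeletal
disorders give ICF = 0.98 — very strong informant agreement; all sixteen
2-dp values reproduce the published table.

Full pipeline on a synthetic survey, from the command line:

```sh
ethnokit simulate --seed 11 --outdir survey
ethnokit report --reports survey/use_reports.csv --species survey/species.csv \
    --category-map survey/category_map.csv --outdir analysis --seed 11
```

This simulates 13,931 deduplicated use reports under the default
study-condition configuration and writes 17 artifacts: `icf_by_category.csv`
(e.g. `Pains,25,2967,0.9919...,0.99` — the simulated Pains category has 25
taxa over 2,967 citations), `fidelity.csv`, per-axis frequency summaries,
the network exports (`incidence.dl` with header
`dl nr=16 nc=115 format=fullmatrix`, GraphML, edge list, `groups.csv`,
`layout.csv`), a markdown report and a `manifest.json` with input digests.
Reruns are byte-identical.

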