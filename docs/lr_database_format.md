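# L-R database format

`cccdiff` reads ligand-receptor databases from a TSV with one interaction
per row and these columns (first six mandatory):

| column | content |
| --- | --- |
| `id` | unique interaction id |
| `ligand_name` | display name of the ligand (complex) |
| `ligand_subunits` | ligand gene symbols, `_`-delimited |
| `receptor_name` | display name of the receptor (complex) |
| `receptor_subunits` | receptor gene symbols, `_`-delimited |
| `pathway` | signaling-family label (exactly one per interaction) |
| `agonists` | soluble agonist genes, `_`-delimited, may be empty |
| `antagonists` | soluble antagonist genes |
| `co_stimulatory` | membrane-bound co-stimulatory co-receptor genes |
| `co_inhibitory` | membrane-bound co-inhibitory co-receptor genes |
| `category` | one of `secreted`, `ecm_receptor`, `cell_contact` |

The `_` delimiter matches the complex-naming convention of common L-R
resources (`NRXN1_NLGN2`); it is configurable in
`read_lr_database(path, delimiter=...)`. Unknown columns are ignored with
a warning; duplicate ids, empty complexes, or one complex name bound to
two different subunit lists are errors. Multi-pathway membership is
rejected at load — pathways must partition the interaction set, because
pathway scores sum their interactions' strengths and a shared interaction
would be double-counted.

## Exporting CellChatDB

No third-party database content ships with this package. From R, the
CellChatDB object can be flattened into this schema:

```r
db <- CellChatDB.human
inter <- db$interaction      # one row per interaction
cplx  <- db$complex          # complex name -> subunit columns
cof   <- db$cofactor         # cofactor name -> gene columns

subunits <- function(name) {
  if (name %in% rownames(cplx)) {
    s <- unlist(cplx[name, ]); paste(s[s != ""], collapse = "_")
  } else name
}
cof_genes <- function(name) {
  if (is.na(name) || name == "") return("")
  g <- unlist(cof[name, ]); paste(g[g != ""], collapse = "_")
}

out <- data.frame(
  id                = rownames(inter),
  ligand_name       = inter$ligand,
  ligand_subunits   = vapply(inter$ligand,   subunits, ""),
  receptor_name     = inter$receptor,
  receptor_subunits = vapply(inter$receptor, subunits, ""),
  pathway           = inter$pathway_name,
  agonists          = vapply(inter$agonist,    cof_genes, ""),
  antagonists       = vapply(inter$antagonist, cof_genes, ""),
  co_stimulatory    = vapply(inter$co_A_receptor, cof_genes, ""),
  co_inhibitory     = vapply(inter$co_I_receptor, cof_genes, ""),
  category          = c(`Secreted Signaling` = "secreted",
                        `ECM-Receptor`       = "ecm_receptor",
                        `Cell-Cell Contact`  = "cell_contact")[inter$annotation]
)
write.table(out, "lr_database.tsv", sep = "\t", quote = FALSE, row.names = FALSE)
```

## Exporting CellPhoneDB

CellPhoneDB distributes `interaction_input.csv`, `complex_input.csv` and
`gene_input.csv`. Map each partner to its gene symbols (via
`complex_input` for complex partners, else `gene_input`), join them with
`_`, and fill `pathway` from the annotation you wish to aggregate by
(CellPhoneDB has no built-in pathway families, so interactions are often
grouped by the receptor family or left one-pathway-per-interaction).
Cofactor columns stay empty; `category` can be derived from the
`secreted`/`integrin` flags.
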