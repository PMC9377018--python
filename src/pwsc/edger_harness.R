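# edgeR comparison arm: TMM normalization + classic exactTest per set.
# Usage: Rscript edger_harness.R <dir> <n_sets>
# Expects counts_<i>.tsv (genes x samples, first column = gene id) and
# groups_<i>.txt (one group label per sample line) for i in 0..n_sets-1;
# writes pvalues_<i>.tsv with columns gene, p_value.

suppressMessages(library(edgeR))

args <- commandArgs(trailingOnly = TRUE)
dir <- args[1]
n_sets <- as.integer(args[2])

for (i in seq_len(n_sets) - 1L) {
  counts <- read.delim(file.path(dir, sprintf("counts_%d.tsv", i)),
                       row.names = 1, check.names = FALSE)
  group <- factor(readLines(file.path(dir, sprintf("groups_%d.txt", i))))
  y <- DGEList(counts = as.matrix(counts), group = group)
  y <- calcNormFactors(y)                 # TMM (default)
  y <- estimateDisp(y)
  et <- exactTest(y)
  out <- data.frame(gene = rownames(et$table), p_value = et$table$PValue)
  write.table(out, file.path(dir, sprintf("pvalues_%d.tsv", i)),
              sep = "\t", row.names = FALSE, quote = FALSE)
}
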