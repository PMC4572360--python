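# Published QA-engine output for the question "what cellular component is
# the location of ARVCF?" (PubMed retrieval): the top-5 ranked GO answers
# of the supervised k-NN classifier (knn) and of two dictionary-based
# classifiers (dict_eagl, dict_gopubmed), with the three curated gold
# cellular-component terms from the protein's UniProtKB record.
# system<TAB>semicolon-joined ranked GO ids
gold	GO:0005634;GO:0005737;GO:0005886
knn	GO:0005634;GO:0005737;GO:0005886;GO:0005911;GO:0005913
dict_eagl	GO:0005912;GO:0005915;GO:0005923;GO:0005886;GO:0005694
dict_gopubmed	GO:0005694;GO:0005737;GO:0016020;GO:0005912;GO:0005886
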