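# taxon	scientific_name	common_names (pipe-separated)	mesh_descriptor
3702	Arabidopsis thaliana	arabidopsis|thale cress|mouse-ear cress	Arabidopsis
9031	Gallus gallus	chicken|chickens	Chickens
9913	Bos taurus	cow|cattle|bovine	Cattle
9606	Homo sapiens	human|humans|man	Humans
10090	Mus musculus	mouse|house mouse|mice	Mice
10116	Rattus norvegicus	rat|norway rat|rats	Rats
7955	Danio rerio	zebrafish|zebra fish|leopard danio	Zebrafish
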