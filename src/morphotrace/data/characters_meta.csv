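char,name,char_class,groups,states
1,"Palp surface",non-reproductive,,"Smooth|Papillose|Ciliated|Rugose"
2,"Inner palpal sheath",non-reproductive,,"Absent|Present"
3,"Outer palpal sheath",non-reproductive,,"Absent|Present"
4,"Median antenna",non-reproductive,,"Absent|Present"
5,"Lateral antenna",non-reproductive,,"Absent|Present"
6,"Prostomial shape",non-reproductive,,"Absent|Present"
7,"Prostomium",non-reproductive,,"Absent|Present"
8,"Tentacular cirri",non-reproductive,,"Absent|Present"
9,"Eyes",non-reproductive,,"Absent|Present"
10,"Segment 1",non-reproductive,,"Absent|Present"
11,"Buccal acicula",non-reproductive,,"Absent|Present"
12,"Notopodial sensory projection",non-reproductive,,"Absent|Present"
13,"Position/distribution of the dorsal cirri",non-reproductive,,"Only on segment 3|On most non-elytrigerous segments|On all segments"
14,"Dorsal tubercles on non-elytrigerous segments",non-reproductive,,"Absent|Present"
15,"Parapodial form",non-reproductive,,"Absent|Present"
16,"Lateral glandular fields",non-reproductive,,"Absent|Present"
17,"Notopodial stylodes",non-reproductive,,"Absent|Present"
18,"Neuropodial stylodes",non-reproductive,,"Absent|Present"
19,"Modified stylode with papillated/adhesive disks",non-reproductive,,"Absent|Present"
20,"Parapodia modified for reproduction",sexual,AG;RG;CG;PG;GG,"Absent|Present"
21,"Proboscis/muscular pharynx",non-reproductive,,"Absent|Present"
22,"Number of segments",non-reproductive,,"Absent|Present"
23,"Prechaetal lobes",non-reproductive,,"Absent|Present"
24,"Notochaetae",non-reproductive,,"Absent|Present"
25,"Simple neurochaetae",non-reproductive,,"Absent|Present"
26,"Neurochaetal spines",non-reproductive,,"Absent|Present"
27,"Unilateral fringed neurochaetae",non-reproductive,,"Absent|Present"
28,"Compound falcigerous neurochaetae",non-reproductive,,"Absent|Present"
29,"Compound spinigerous neurochaetae",non-reproductive,,"Absent|Present"
30,"Elytra",non-reproductive,,"Absent|Present"
31,"Midventral pores",non-reproductive,,"Absent|Present"
32,"Protruding notoacicula",non-reproductive,,"Absent|Present"
33,"Infra-acicular simple chaetae",non-reproductive,,"Absent|Present"
34,"Elongation of dorsal cirri on segment 3",non-reproductive,,"Absent|Present"
35,"Prechaetal lobes divided",non-reproductive,,"Absent|Present"
36,"Long-bladed compound chaetae",non-reproductive,,"Absent|Present"
37,"Fusion of copulatory organ and parapodial lobe",sexual,PG,"Absent|Present"
38,"Spiral structure of the copulatory organ",sexual,RG;CG;PG,"Absent|Present"
39,"Inferior stem of copulatory organ derived from bidigitate process",sexual,AG;RG;CG,"Absent|Present"
40,"Bidigitate process of copulatory organ homologous to inferior stem",sexual,AG;RG;CG,"Absent|Present"
41,"Sheath-like arc of the copulatory organ",sexual,AG;RG;CG,"Absent|Present"
42,"Cuticular plate of the copulatory organ",sexual,RG;CG,"Absent|Present"
43,"Elongated ventral cirri of the copulatory segments",sexual,RG;CG,"Absent|Present"
44,"Spinous papillae present on copulatory structures",sexual,PG,"Absent|Present"
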