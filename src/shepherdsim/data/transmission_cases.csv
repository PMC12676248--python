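case_id,smc_type,offspring_ratio,offspring_phenotype,parent_ratio,parent_phenotype,origin,mechanism,source
1,min (2)(:p11.1→q21.1:),75%,Prenatal early pregnancy loss,90% Mosaic,Phenotypically normal,maternal,Not reported in the publication,PMID:16276087
2,r (3)(::p10→q13.1::),41%,Phenotypically normal,33% Mosaic,Phenotypically normal,maternal,Not reported in the publication,PMID:11241494
3,r (3)(::p10→q12::),56%,Normal autopsy post-termination,5%–6% Mosaic,Phenotypically normal,maternal,Not reported in the publication,PMID:11241494
4,r (8)(::p11.21→q11.1::),86%,Phenotypically normal,100%,Phenotypically normal,maternal,Not reported in the publication,PMID:13680362
5,idic (22)+der (22),82%,Normal autopsy post-termination,4% Mosaic,Phenotypically normal,paternal,Not reported in the publication,PMID:13680362
6,+r (8)(p11;q12),86%,Phenotypically normal,100%,Phenotypically normal,maternal,Not reported in the publication,PMID:11354630
7,min (9)(:p12→q11:),38%,Unrecorded data,73% Mosaic,Phenotypically normal,maternal,Not reported in the publication,PMID:8522323
8,min (9),80%,Phenotypically normal,70% Mosaic,Phenotypically normal,maternal,Hypothesized formation mechanisms,PMID:7767653
9,mar (10)(:p11.21→q11.1:),49%,"Phenotypically normal (a sister with the same karyotype, 77% mosaic, has a normal phenotype)",61% Mosaic,Phenotypically normal,maternal,Not reported in the publication,PMID:26270802
10,r (11),60%,CREST syndrome (a subtype of systemic sclerosis) at age 34,59% Mosaic,Progressive systemic sclerosis from age 59 developing into complete CREST syndrome,paternal,Not reported in the publication,PMID:1582251
11,min (12)(:p11.1→q12:),77%,Phenotypically normal,25% Mosaic,Phenotypically normal,paternal,Not reported in the publication,sSMC-DB
12,min (12)(:p11.1→q11:),42.5%,Phenotypically normal,100%,Phenotypically normal,maternal,Not reported in the publication,sSMC-DB
13,min (14)(pter→q1?0),19%,Phenotypically normal,100%,Phenotypically normal,maternal,Not reported in the publication,PMID:7747772
14,mar (14),57%,Phenotypically normal,100%,Phenotypically normal,maternal,Hypothesized formation mechanisms,PMID:7767653
15,inv dup (15)(q11),96%,Phenotypically normal (a sister carries the same SMC as the father and has no abnormal phenotype),100%,Phenotypically normal,paternal,Not reported in the publication,sSMC-DB
16,inv dup (15)(q11.1),98%,Phenotypically normal,Mosaic (proportion not recorded),Phenotypically normal,maternal,Not reported in the publication,sSMC-DB
17,inv dup (15)(q11.1),83%,Phenotypically normal,100%,No abnormal phenotype observed in family members,Familial,Not reported in the publication,sSMC-DB
18,min (15)(:p11.1→q11.1:),80%,Phenotypically normal,100%,Phenotypically normal (inherited from the grandmother who shows no abnormal phenotype),maternal,Not reported in the publication,sSMC-DB
19,r (15)(::p11.2→q13.1::),78.7%,Phenotypically normal,10% Mosaic,Phenotypically normal,maternal,Not reported in the publication,PMID:23295254
20,r (15),72%,Phenotypically normal,100%,Phenotypically normal,maternal,Not reported in the publication,PMID:16762822
21,mar (15),65%,Phenotypically normal,15% Mosaic,Phenotypically normal,maternal,Not reported in the publication,PMID:3688018
22,mar (15),45%,Phenotypically normal,100%,Phenotypically normal,paternal,Not reported in the publication,PMID:16900777
23,min (16)(:p11.2→q11.2:),50%,Phenotypically normal,100%,Phenotypically normal,maternal,Not reported in the publication,sSMC-DB
24,mar (16)(:p11.2→q12.1:),60%,Phenotypically normal,100%,Phenotypically normal,maternal,Not reported in the publication,PMID:28871159
25,min (16)(:p11.1→q12.1:),20%,Phenotypically normal (one of a twin pregnancy; the other fetus has no chromosomal abnormalities),50% Mosaic,Phenotypically normal,maternal,Not reported in the publication,sSMC-DB
26,min (16)(:p11.1→q11.1:),90%–97%,Phenotypically normal,4%–10% Mosaic,Phenotypically normal,paternal,Not reported in the publication,literature
27,min (18)(:p11.21→q11.1:),74%,Phenotypically normal,26% Mosaic,Phenotypically normal,maternal,Not reported in the publication,PMID:17317954
28,mar (18)(:p11.21→q11.1:),80%,Phenotypically normal (gave birth to a daughter with the same SMC who shows no abnormal phenotype),100%,Phenotypically normal,paternal,Not reported in the publication,PMID:18252220
29,min (18)(:p11.1→q11.1:),65%,Phenotypically normal,26% Mosaic,Phenotypically normal,maternal,Not reported in the publication,PMID:19816880
30,mar (19)(:p12→q13.11:),41%,Phenotypically normal,100%,Phenotypically normal,maternal,Not reported in the publication,PMID:39026136
31,r (21)(::p1?2→q11.2::),30%,Phenotypically normal,100%,Phenotypically normal,paternal,Not reported in the publication,sSMC-DB
32,inv dup (21)(q21.1),47%,Phenotypically normal,22% Mosaic,Phenotypically normal,maternal,Not reported in the publication,PMID:32514314
33,r (22)(::p12→q11.21::),74%,Phenotypically normal,100%,Phenotypically normal,paternal,Not reported in the publication,PMID:33632263
34,Min (X)(:p11.1→q11.1:),70%,Phenotypically normal,100%,Phenotypically normal,maternal,Not reported in the publication,PMID:38259626
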