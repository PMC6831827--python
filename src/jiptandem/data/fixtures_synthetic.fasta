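>JIP3_HUMAN_NTER synthetic stand-in; human JIP3 N-terminus 1-187 (accession NP_055948.2 in the source study)
MSDTSVSLKEVSTEGLTQAVQSAVLAKAVQELAGQIYNKFEELISEYDEEVVLELMPQVV
KVLQELAKVLKENQEHEELREVKQELEELQNRISRVEKKLQRMQEKLNSLEKRLRQVQRK
IENLERKLQEVQNRLSRLEKKLQRMQEKLNSVEKRIRQLQRKLENVEAKLQELQNRLEQL
SKELAEK
>JIP4_HUMAN_NTER synthetic stand-in; human JIP4 N-terminus 1-182 (accession NP_001123999.1 in the source study)
MADSSLVKQSEDFTQVSSVLAKSVQDLAGQIYNRFEELISDYDEEVVLDLMPQVVRVLQE
LARVLKENQEHEELSEVKKELQELQTRISKVEKKLQSMQERLNTLEKRLRSVQRNIETLE
RKLQSVQNRLSKLEKKLQSMQEKLNTVEKRIRKLQRKLESVEAKLQTLQNRLEQLSKELA
EK
>JIP3_MOUSE_NTER synthetic stand-in; mouse JIP3 N-terminus 1-187 (NP_038959.2; single Lys98Arg difference vs human)
MSDTSVSLKEVSTEGLTQAVQSAVLAKAVQELAGQIYNKFEELISEYDEEVVLELMPQVV
KVLQELAKVLKENQEHEELREVKQELEELQNRISRVERKLQRMQEKLNSLEKRLRQVQRK
IENLERKLQEVQNRLSRLEKKLQRMQEKLNSVEKRIRQLQRKLENVEAKLQELQNRLEQL
SKELAEK
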