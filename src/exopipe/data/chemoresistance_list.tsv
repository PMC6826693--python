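mirna	drug	direction
hsa-miR-150	cisplatin	up
hsa-miR-342-3p	cisplatin	up
hsa-miR-320	cisplatin	up
hsa-let-7g	cisplatin	down
hsa-miR-590-5p	cisplatin	up
hsa-miR-25	cisplatin	up
hsa-miR-20a	cisplatin	up
hsa-miR-20a	doxorubicin	up
hsa-miR-146b	cisplatin	up
hsa-miR-146b	doxorubicin	down
hsa-miR-146b	vincristine	down
hsa-miR-106b	doxorubicin	up
hsa-miR-199a-3p	doxorubicin	down
hsa-miR-195	cisplatin	down
hsa-miR-195	etoposide	down
hsa-miR-26a	doxorubicin	down
hsa-miR-483-5p	cisplatin	up
hsa-let-7d	cisplatin	down
hsa-let-7d	doxorubicin	down
hsa-miR-106a	cisplatin	up
hsa-miR-106a	doxorubicin	up
hsa-let-7e	doxorubicin	up
hsa-miR-21	cisplatin	up
hsa-miR-21	etoposide	up
hsa-miR-21	doxorubicin	up
hsa-miR-17	cisplatin	up
hsa-miR-15b	cisplatin	up
hsa-miR-15b	vincristine	down
hsa-miR-24	cisplatin	up
hsa-miR-24	etoposide	down
hsa-miR-24	doxorubicin	up
hsa-miR-30c	cisplatin	up
hsa-miR-30c	doxorubicin	down
hsa-miR-345	cisplatin	down
hsa-miR-29a	cisplatin	down
hsa-miR-29a	etoposide	down
hsa-miR-16	etoposide	down
hsa-miR-223	doxorubicin	up
hsa-miR-223	carboplatin	up
hsa-miR-222	cisplatin	up
hsa-miR-222	doxorubicin	up
hsa-miR-222	carboplatin	up
hsa-miR-146a	cisplatin	down
hsa-miR-146a	etoposide	down
hsa-let-7b	cisplatin	down
hsa-let-7b	doxorubicin	down
hsa-miR-125a-5p	cisplatin	up
hsa-miR-155	cisplatin	up
hsa-miR-155	doxorubicin	up
hsa-miR-486	cisplatin	up
hsa-miR-126	vincristine	down
hsa-miR-191	cisplatin	up
hsa-miR-191	doxorubicin	up
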